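"""Closed-form 2D packing relations and bead-mass bookkeeping.

The micellar phases admit simple geometric size predictions from the
hydrophilic chain radii: a PEO-cored 2D micelle of 6 PEO-PDPA diblocks
ringed by 12 triblocks spans about eight PDPA radii, while the inverted
micelle of one PMPC-PDPA diblock ringed by 6 triblocks spans about two
PMPC radii.  The default radii are back-solved from the measured 7 nm
and 5.5 nm domain sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Monomer molar masses in amu.
MONOMER_MASS_MPC = 295.27
MONOMER_MASS_DPA = 213.32
MONOMER_MASS_EO = 44.05


@dataclass(frozen=True)
class ChainGeometry:
    """Hydrophilic chain radii and chain-occupancy areas (user-supplied)."""

    r_pdpa: float = 7.0 / 8.0   # nm
    r_pmpc: float = 2.75        # nm
    a_pmpc: float = 1.0         # nm^2
    a_peo: float = 0.6          # nm^2

    def __post_init__(self):
        if min(self.r_pdpa, self.r_pmpc, self.a_pmpc, self.a_peo) <= 0:
            raise ValueError("chain radii and areas must be positive")


def micelle1_diameter(r_pdpa: float) -> float:
    """Diameter of the PEO-cored 2D micelle: eight PDPA radii."""
    if r_pdpa < 0:
        raise ValueError("radius must be non-negative")
    return 8.0 * r_pdpa


def micelle2_diameter(r_pmpc: float) -> float:
    """Diameter of the inverted (PMPC-cored) 2D micelle: two PMPC radii."""
    if r_pmpc < 0:
        raise ValueError("radius must be non-negative")
    return 2.0 * r_pmpc


def area_mismatch(a_pmpc: float, a_peo: float) -> float:
    """Packing mismatch between the hydrophilic blocks: min/max area ratio."""
    if a_pmpc <= 0 or a_peo <= 0:
        raise ValueError("areas must be positive")
    return min(a_pmpc, a_peo) / max(a_pmpc, a_peo)


def bead_mass(block_counts, monomer_masses, scale: float = 0.1) -> float:
    """Coarse-grained bead mass: scaled weighted sum of block masses.

    ``bead_mass((25, 74), (m_MPC, m_DPA))`` gives the PMPC-PDPA diblock
    bead at the 1/10 mass mapping.
    """
    if len(block_counts) != len(monomer_masses):
        raise ValueError("counts and masses must have equal length")
    if any(c <= 0 for c in block_counts) or any(m <= 0 for m in monomer_masses):
        raise ValueError("counts and masses must be positive")
    return scale * sum(c * m for c, m in zip(block_counts, monomer_masses))


def geometry_report(geom: ChainGeometry | None = None) -> dict:
    """Micelle-size predictions and formula bead masses for a geometry."""
    geom = geom or ChainGeometry()
    return {
        "micelle1_diameter_nm": micelle1_diameter(geom.r_pdpa),
        "micelle2_diameter_nm": micelle2_diameter(geom.r_pmpc),
        "area_mismatch": area_mismatch(geom.a_pmpc, geom.a_peo),
        "m_pmpc_diblock_amu": bead_mass((25, 74),
                                        (MONOMER_MASS_MPC, MONOMER_MASS_DPA)),
        "m_peo_block_amu": bead_mass((45, 30),
                                     (MONOMER_MASS_EO, MONOMER_MASS_DPA)),
        "m_pmpc_triblock_amu": bead_mass((12, 30),
                                         (MONOMER_MASS_MPC, MONOMER_MASS_DPA)),
    }
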