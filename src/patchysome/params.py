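"""Force-field and integrator parameter containers.

Units follow the GROMACS convention throughout the package: lengths in
nm, times in ps, masses in amu (g/mol), energies in kJ/mol.  With these
units kinetic energy ``m v^2 / 2`` comes out directly in kJ/mol for
velocities in nm/ps, so no unit conversion appears anywhere in the
dynamics code.

The simulation operates at a 1/10 scale: simulated lengths represent one
tenth of the physical inter-chain separations and bead masses one tenth
of the copolymer masses.  ``length_scale`` (default 10) converts
simulated nm to physical nm for comparison with micrographs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

#: Boltzmann constant in kJ/mol/K (CODATA).
KB = 0.00831446261815324

# Chemical kinds of the two hydrophilic blocks.
KIND_PMPC = 0
KIND_PEO = 1

# Species codes; ``code % 2`` gives the chemical kind.
PMPC_DI = 0   # lone PMPC bead of a PMPC-PDPA diblock
PEO_DI = 1    # lone PEO bead of a PEO-PDPA diblock (ternary systems)
PMPC_TRI = 2  # PMPC bead of a PEO-PDPA-PMPC triblock
PEO_TRI = 3   # PEO bead of a PEO-PDPA-PMPC triblock

SPECIES_NAMES = {PMPC_DI: "PMPC_di", PEO_DI: "PEO_di",
                 PMPC_TRI: "PMPC_tri", PEO_TRI: "PEO_tri"}
SPECIES_CODES = {v: k for k, v in SPECIES_NAMES.items()}


@dataclass(frozen=True)
class ForceFieldParams:
    """Interaction constants of the two-kind bead model.

    Same-kind bead pairs attract through a 12-6 Lennard-Jones potential
    (PMPC: ``eps_pmpc``/``sigma_pmpc``; PEO: ``eps_peo``/``sigma_peo``).
    Unlike pairs repel through ``eps_cross * (sigma_pmpc / r)**12``.
    Bonded triblock bead pairs feel a flat-bottom restraint that is zero
    below ``d_max`` and harmonic (force constant ``k_bond``) beyond it.

    All nonbonded terms are truncated and shifted to zero at
    ``lj_cutoff_factor`` times the pair's sigma (the cross term uses
    ``sigma_pmpc``).

    The PEO well depth and the cross-repulsion prefactor default to the
    PMPC well depth (1 kJ/mol); both are configurable.
    """

    eps_pmpc: float = 1.0        # kJ/mol
    eps_peo: float = 1.0         # kJ/mol
    sigma_pmpc: float = 0.3      # nm
    sigma_peo: float = 0.2       # nm
    eps_cross: float = 1.0       # kJ/mol, prefactor of (sigma_pmpc/r)**12
    k_bond: float = 1.0e4        # kJ/mol/nm^2
    d_max: float = 1.5           # nm, flat-bottom width of the bond restraint
    lj_cutoff_factor: float = 2.5
    length_scale: float = 10.0   # simulated nm -> physical nm
    mass_scale: float = 10.0     # simulated amu -> physical amu

    def __post_init__(self) -> None:
        for name in ("eps_pmpc", "eps_peo", "sigma_pmpc", "sigma_peo",
                     "eps_cross", "k_bond", "d_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.d_max <= self.sigma_pmpc:
            raise ValueError("d_max must exceed sigma_pmpc")
        if self.lj_cutoff_factor < 2.0:
            raise ValueError("lj_cutoff_factor must be >= 2")

    @property
    def cutoff_pmpc(self) -> float:
        return self.lj_cutoff_factor * self.sigma_pmpc

    @property
    def cutoff_peo(self) -> float:
        return self.lj_cutoff_factor * self.sigma_peo

    @property
    def cutoff_cross(self) -> float:
        return self.lj_cutoff_factor * self.sigma_pmpc

    @property
    def max_cutoff(self) -> float:
        return max(self.cutoff_pmpc, self.cutoff_peo, self.cutoff_cross)


@dataclass(frozen=True)
class SpeciesMasses:
    """Bead masses in amu, at the 1/10 mass scale.

    ``m_pmpc_bead`` is the lone PMPC bead of the PMPC-PDPA diblock,
    ``m_peo_bead`` the PEO bead and ``m_pmpc_tri_bead`` the PMPC bead of
    the two-bead triblock.  A lone PEO diblock bead (ternary systems)
    reuses ``m_peo_bead``, whose composition formula corresponds to a
    45-unit PEO chain with its hydrophobic share.
    """

    m_pmpc_bead: float = 2313.0     # amu
    m_peo_bead: float = 774.0       # amu
    m_pmpc_tri_bead: float = 993.0  # amu

    def __post_init__(self) -> None:
        if min(self.m_pmpc_bead, self.m_peo_bead, self.m_pmpc_tri_bead) <= 0:
            raise ValueError("bead masses must be positive")

    def for_species(self, species_code: int) -> float:
        return {
            PMPC_DI: self.m_pmpc_bead,
            PEO_DI: self.m_peo_bead,
            PMPC_TRI: self.m_pmpc_tri_bead,
            PEO_TRI: self.m_peo_bead,
        }[species_code]


@dataclass(frozen=True)
class IntegratorSettings:
    """Langevin integration settings.

    ``t_friction`` is the inverse friction constant tau (ps); the
    friction coefficient of bead i is ``gamma_i = m_i / tau`` so the free
    diffusion constant is ``D_i = kB * T * tau / m_i``.
    """

    dt: float = 0.002          # ps (2 fs)
    t_friction: float = 1.0    # ps
    temperature: float = 300.0 # K
    n_steps: int = 0
    seed: int = 0
    save_every: int = 1000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_friction <= 0:
            raise ValueError("t_friction must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


def _from_mapping(cls, mapping):
    names = {f.name for f in fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise KeyError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path: str | Path) -> dict:
    """Read a YAML run configuration.

    Recognised top-level sections: ``forcefield``, ``masses``,
    ``integrator`` (each a flat mapping whose keys mirror the dataclass
    fields above) and ``system`` (free-form: n, radius, composition,
    seed).  Missing sections fall back to the published defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {
        "forcefield": _from_mapping(ForceFieldParams, raw.get("forcefield", {})),
        "masses": _from_mapping(SpeciesMasses, raw.get("masses", {})),
        "integrator": _from_mapping(IntegratorSettings, raw.get("integrator", {})),
        "system": dict(raw.get("system", {})),
    }


def dump_config(path: str | Path, forcefield: ForceFieldParams | None = None,
                masses: SpeciesMasses | None = None,
                integrator: IntegratorSettings | None = None,
                system: dict | None = None) -> None:
    doc = {
        "forcefield": asdict(forcefield or ForceFieldParams()),
        "masses": asdict(masses or SpeciesMasses()),
        "integrator": asdict(integrator or IntegratorSettings()),
        "system": system or {},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
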