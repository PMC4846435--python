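"""Initial configurations: bead lattice on the sphere and species assignment.

Beads are placed on a spherical Fibonacci (golden-angle) lattice, which
is deterministic and quasi-uniform: at the published density (65539
beads on a 19.2 nm sphere) the ideal hexagonal spacing is 0.286 nm and
the realized mean nearest-neighbor distance about 0.26 nm — inside one
PMPC Lennard-Jones sigma, so the surface starts out slightly
compressed.  Species and triblock bonds are then assigned
at random given a seed, with the two beads of each triblock placed on
neighboring lattice sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .params import (KB, PEO_DI, PEO_TRI, PMPC_DI, PMPC_TRI,
                     SpeciesMasses)

logger = logging.getLogger(__name__)

#: Published bead count and sphere radius (nm) of the full-scale system.
PAPER_N = 65539
PAPER_RADIUS = 19.2


@dataclass
class SurfaceConfiguration:
    """Bead positions, species, triblock bonds and velocities on a sphere.

    Invariants: every position has norm ``radius``; velocities are
    tangential; each bond pairs one PMPC_tri bead with one PEO_tri bead
    and no bead appears in two bonds.
    """

    radius: float
    positions: np.ndarray          # (n, 3) nm
    species: np.ndarray            # (n,) int codes, see params
    bonds: np.ndarray              # (nb, 2) int indices (PMPC_tri, PEO_tri)
    velocities: np.ndarray         # (n, 3) nm/ps, tangential
    masses: np.ndarray             # (n,) amu
    seed: int = 0

    @property
    def n(self) -> int:
        return len(self.positions)

    def kinds(self) -> np.ndarray:
        """Chemical kind per bead: 0 = PMPC, 1 = PEO."""
        return self.species % 2

    def copy(self) -> "SurfaceConfiguration":
        return SurfaceConfiguration(
            radius=self.radius,
            positions=self.positions.copy(),
            species=self.species.copy(),
            bonds=self.bonds.copy(),
            velocities=self.velocities.copy(),
            masses=self.masses.copy(),
            seed=self.seed,
        )

    def validate(self, tol: float = 1e-6) -> None:
        r = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(r, self.radius, rtol=0, atol=tol * self.radius):
            raise ValueError("bead positions are not on the sphere")
        radial_v = np.abs(np.sum(self.positions * self.velocities, axis=1)) / self.radius
        if self.velocities.size and radial_v.max() > 1e-6 * (1.0 + np.abs(self.velocities).max()):
            raise ValueError("velocities are not tangential")
        counts = np.bincount(self.bonds.ravel(), minlength=self.n) if len(self.bonds) else np.zeros(self.n, int)
        tri = np.isin(self.species, (PMPC_TRI, PEO_TRI))
        if np.any(counts[tri] != 1) or np.any(counts[~tri] != 0):
            raise ValueError("bond topology inconsistent with species labels")
        for i, j in self.bonds:
            if {self.species[i], self.species[j]} != {PMPC_TRI, PEO_TRI}:
                raise ValueError("each bond must pair a PMPC_tri with a PEO_tri bead")


@dataclass(frozen=True)
class CompositionSpec:
    """Molar composition of the copolymer mixture.

    ``frac_triblock`` is the molar fraction of PEO-PDPA-PMPC triblock
    molecules (each contributing two beads); ``frac_peo_diblock`` the
    molar fraction of lone-bead PEO-PDPA diblocks (0 for binary
    mixtures); the remainder are PMPC-PDPA diblocks.  ``n_beads`` is the
    total bead count, held constant across compositions.
    """

    frac_triblock: float
    n_beads: int
    frac_peo_diblock: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_triblock <= 1.0 and 0.0 <= self.frac_peo_diblock <= 1.0):
            raise ValueError("molar fractions must lie in [0, 1]")
        if self.frac_triblock + self.frac_peo_diblock > 1.0 + 1e-12:
            raise ValueError("molecule fractions exceed 1")
        if self.n_beads < 1:
            raise ValueError("need at least one bead")


def ideal_hex_spacing(n: int, radius: float) -> float:
    """Lattice constant of an ideal hexagonal packing of n points on the sphere."""
    return float(np.sqrt(8.0 * np.pi * radius**2 / (np.sqrt(3.0) * n)))


def fibonacci_lattice(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on a sphere via the golden-angle spiral.

    Nearest-neighbor distances stay within roughly +-30% of the ideal
    hexagonal spacing for any n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n == 1:
        return np.array([[0.0, 0.0, radius]])
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden_angle = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden_angle * i
    pts = np.column_stack((rho * np.cos(theta), rho * np.sin(theta), z))
    return radius * pts


def scaled_bead_count(radius: float, reference_n: int = PAPER_N,
                      reference_radius: float = PAPER_RADIUS) -> int:
    """Bead count preserving the published areal density on a smaller sphere."""
    return int(round(reference_n * (radius / reference_radius) ** 2))


def triblock_count(frac_triblock: float, n_beads: int) -> int:
    """Number of triblock molecules for a molar fraction x at fixed bead count.

    With n_t triblocks (2 beads each) and n_s single-bead molecules,
    2*n_t + n_s = n and the molar fraction is n_t / (n_t + n_s), giving
    n_t = x*n / (1 + x), rounded to the nearest integer.
    """
    return int(round(frac_triblock * n_beads / (1.0 + frac_triblock)))


def _pair_triblock_sites(positions: np.ndarray, n_t: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Choose n_t disjoint pairs of neighboring lattice sites.

    Greedy pass: visit sites in random order and pair each free site
    with its nearest free site among its 8 nearest lattice neighbors.
    Any shortfall is made up by pairing the remaining free sites with
    their mutually nearest free partners, which on a dense lattice are
    still far closer than the d_max restraint width.
    """
    n = len(positions)
    tree = cKDTree(positions)
    k = min(9, n)
    _, nbr = tree.query(positions, k=k)
    order = rng.permutation(n)
    used = np.zeros(n, bool)
    pairs = []
    for i in order:
        if len(pairs) == n_t:
            break
        if used[i]:
            continue
        for j in nbr[i, 1:]:
            if not used[j]:
                used[i] = used[j] = True
                pairs.append((i, int(j)))
                break
    while len(pairs) < n_t:
        free = np.flatnonzero(~used)
        if len(free) < 2:
            raise ValueError("not enough free sites to host all triblocks")
        ftree = cKDTree(positions[free])
        _, jloc = ftree.query(positions[free[0]], k=2)
        i, j = int(free[0]), int(free[jloc[1]])
        used[i] = used[j] = True
        pairs.append((i, j))
    return np.array(pairs, int).reshape(-1, 2)


def maxwell_tangential_velocities(positions: np.ndarray, radius: float,
                                  masses: np.ndarray, temperature: float,
                                  rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities projected onto the local tangent plane."""
    sigma = np.sqrt(KB * temperature / masses)[:, None]
    v = rng.standard_normal(positions.shape) * sigma
    normal = positions / radius
    v -= np.sum(v * normal, axis=1, keepdims=True) * normal
    return v


def assign_species(positions: np.ndarray, radius: float, comp: CompositionSpec,
                   seed: int, masses: SpeciesMasses | None = None,
                   temperature: float = 300.0,
                   d_max: float = 1.5) -> SurfaceConfiguration:
    """Randomly assign species and triblock bonds on a lattice.

    Triblock bead pairs occupy neighboring lattice sites (initial
    separation well below ``d_max``); which end of the pair carries the
    PEO bead is random.  Remaining sites become single-bead diblocks,
    split between PMPC-PDPA and PEO-PDPA by the requested molecule
    fractions.  Deterministic given ``seed``.
    """
    masses = masses or SpeciesMasses()
    n = len(positions)
    if n != comp.n_beads:
        raise ValueError("positions length does not match composition n_beads")
    rng = np.random.default_rng(seed)
    n_t = triblock_count(comp.frac_triblock, n)
    if 2 * n_t > n:
        n_t = n // 2
        logger.warning("composition rounded down to %d triblocks to fit %d beads", n_t, n)

    species = np.full(n, PMPC_DI, dtype=np.int64)
    bonds = np.empty((0, 2), dtype=np.int64)
    if n_t > 0:
        pairs = _pair_triblock_sites(positions, n_t, rng)
        flip = rng.random(n_t) < 0.5
        pmpc_end = np.where(flip, pairs[:, 1], pairs[:, 0])
        peo_end = np.where(flip, pairs[:, 0], pairs[:, 1])
        species[pmpc_end] = PMPC_TRI
        species[peo_end] = PEO_TRI
        bonds = np.column_stack((pmpc_end, peo_end)).astype(np.int64)
        # guarantee initial separations inside the flat-bottom region
        sep = np.linalg.norm(positions[bonds[:, 0]] - positions[bonds[:, 1]], axis=1)
        bad = np.flatnonzero(sep >= 0.9 * d_max)
        if len(bad):
            logger.warning("relocating %d triblock partner beads closer than d_max", len(bad))
            positions = positions.copy()
            a = ideal_hex_spacing(n, radius)
            for b in bad:
                i, j = bonds[b]
                t = rng.standard_normal(3)
                t -= t @ positions[i] / radius**2 * positions[i]
                t *= a / np.linalg.norm(t)
                p = positions[i] + t
                positions[j] = radius * p / np.linalg.norm(p)

    singles = np.flatnonzero(species == PMPC_DI)
    n_molecules = n - n_t
    n_peo_di = int(round(comp.frac_peo_diblock * n_molecules))
    n_peo_di = min(n_peo_di, len(singles))
    if n_peo_di > 0:
        chosen = rng.choice(singles, size=n_peo_di, replace=False)
        species[chosen] = PEO_DI

    bead_masses = np.array([masses.for_species(s) for s in species])
    velocities = maxwell_tangential_velocities(positions, radius, bead_masses,
                                               temperature, rng)
    cfg = SurfaceConfiguration(radius=radius, positions=np.asarray(positions, float),
                               species=species, bonds=bonds,
                               velocities=velocities, masses=bead_masses, seed=seed)
    cfg.validate()
    return cfg


def build_configuration(n: int, radius: float, comp_frac_triblock: float,
                        seed: int, frac_peo_diblock: float = 0.0,
                        masses: SpeciesMasses | None = None,
                        temperature: float = 300.0) -> SurfaceConfiguration:
    """Convenience: Fibonacci lattice + species assignment in one call."""
    comp = CompositionSpec(frac_triblock=comp_frac_triblock, n_beads=n,
                           frac_peo_diblock=frac_peo_diblock)
    pos = fibonacci_lattice(n, radius)
    return assign_species(pos, radius, comp, seed, masses=masses,
                          temperature=temperature)
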