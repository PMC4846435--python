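"""Domain identification and spacing statistics on the sphere.

Domains are single-linkage clusters (connected components under a chord
distance cutoff) of the beads of one chemical kind.  For each domain we
report a center (normalized vector mean, back on the sphere), an
area-equivalent diameter, and the per-center nearest-neighbor spacing
statistic: for every center, the shortest distance to any other center;
the mean and sample SD of those minima are the reported spacing.

Simulated distances are one tenth of the physical ones; multiply by the
force field's ``length_scale`` (default 10) to compare with micrograph
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .params import KIND_PEO, KIND_PMPC
from .sphere_init import SurfaceConfiguration

PHASE_LABELS = ("micellar_PEO", "bicontinuous", "micellar_PMPC",
                "disordered", "uniform")

#: Clustering cutoff as a multiple of the species's LJ sigma: just above
#: first-neighbor contact, below the second-neighbor shell at lattice density.
DEFAULT_CUTOFF_FACTOR = 1.5


class InsufficientPointsError(ValueError):
    """Raised when a statistic needs more points than were supplied."""


class UndefinedCenterError(ValueError):
    """Raised when a cluster's vector mean vanishes (antipodally balanced)."""


@dataclass
class DomainSet:
    """Clusters of one chemical kind with centers, sizes and spacing."""

    kind: int
    clusters: list                # list of np.ndarray bead indices
    centers: np.ndarray           # (k, 3) points on the sphere
    sizes: np.ndarray             # (k,) area-equivalent diameters, sim nm
    spacing_mean: float           # sim nm (geodesic), nan if < 2 centers
    spacing_sd: float
    radius: float

    @property
    def n_domains(self) -> int:
        return len(self.clusters)

    def bead_counts(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters], int)


def cluster_species(config: SurfaceConfiguration, kind: int,
                    cutoff: float) -> list:
    """Single-linkage clusters of all beads of one chemical kind.

    Returns a list of index arrays into ``config.positions`` (not into
    the kind subset).  Beads closer than ``cutoff`` (chord distance) are
    linked; clusters are the connected components.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    idx = np.flatnonzero(config.kinds() == kind)
    if len(idx) == 0:
        return []
    pts = config.positions[idx]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    m = len(idx)
    if len(pairs):
        graph = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                           shape=(m, m))
    else:
        graph = coo_matrix((m, m))
    n_comp, labels = connected_components(graph, directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def cluster_center(cluster: np.ndarray, config: SurfaceConfiguration) -> np.ndarray:
    """Normalized vector mean of a cluster's positions, rescaled to the sphere."""
    if len(cluster) == 0:
        raise ValueError("cluster is empty")
    mean = config.positions[cluster].mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-9 * config.radius:
        raise UndefinedCenterError("cluster is antipodally balanced")
    return config.radius * mean / norm


def geodesic_distances_from_chords(chords: np.ndarray, radius: float) -> np.ndarray:
    ratio = np.clip(chords / (2.0 * radius), -1.0, 1.0)
    return 2.0 * radius * np.arcsin(ratio)


def nn_spacing(centers: np.ndarray, metric: str = "euclidean",
               radius: float | None = None) -> tuple[float, float]:
    """Per-center shortest distance to any other center: mean and sample SD.

    ``metric='geodesic'`` converts chord lengths to great-circle arcs on
    a sphere of the given radius (nearest neighbors are identical under
    both metrics since the arc is monotone in the chord).
    """
    centers = np.asarray(centers, float)
    if len(centers) < 2:
        raise InsufficientPointsError("need at least 2 centers for spacing")
    tree = cKDTree(centers)
    dist, _ = tree.query(centers, k=2)
    minima = dist[:, 1]
    if metric == "geodesic":
        if radius is None:
            raise ValueError("geodesic metric requires the sphere radius")
        minima = geodesic_distances_from_chords(minima, radius)
    elif metric != "euclidean":
        raise ValueError(f"unknown metric {metric!r}")
    return float(np.mean(minima)), float(np.std(minima, ddof=1))


def domain_size(cluster: np.ndarray, config: SurfaceConfiguration) -> float:
    """Area-equivalent diameter 2*sqrt(A/pi), with A = bead share of the sphere."""
    if len(cluster) == 0:
        raise ValueError("cluster is empty")
    area_per_bead = 4.0 * np.pi * config.radius**2 / config.n
    area = len(cluster) * area_per_bead
    return float(2.0 * np.sqrt(area / np.pi))


def _cutoff_for_kind(kind: int, sigma_pmpc: float, sigma_peo: float,
                     factor: float = DEFAULT_CUTOFF_FACTOR) -> float:
    return factor * (sigma_pmpc if kind == KIND_PMPC else sigma_peo)


def analyze_domains(config: SurfaceConfiguration, kind: int,
                    cutoff: float | None = None,
                    sigma_pmpc: float = 0.3, sigma_peo: float = 0.2) -> DomainSet:
    """Cluster one chemical kind and compute centers, sizes and spacing."""
    if cutoff is None:
        cutoff = _cutoff_for_kind(kind, sigma_pmpc, sigma_peo)
    clusters = cluster_species(config, kind, cutoff)
    if not clusters:
        return DomainSet(kind=kind, clusters=[], centers=np.empty((0, 3)),
                         sizes=np.empty(0), spacing_mean=np.nan,
                         spacing_sd=np.nan, radius=config.radius)
    centers = np.array([cluster_center(c, config) for c in clusters])
    sizes = np.array([domain_size(c, config) for c in clusters])
    if len(centers) >= 2:
        mean, sd = nn_spacing(centers, metric="geodesic", radius=config.radius)
    else:
        mean, sd = np.nan, np.nan
    return DomainSet(kind=kind, clusters=clusters, centers=centers,
                     sizes=sizes, spacing_mean=mean, spacing_sd=sd,
                     radius=config.radius)


def largest_cluster_fraction(config: SurfaceConfiguration, kind: int,
                             cutoff: float) -> float:
    """Fraction of a kind's beads sitting in its largest cluster (nan if absent)."""
    clusters = cluster_species(config, kind, cutoff)
    if not clusters:
        return np.nan
    counts = np.array([len(c) for c in clusters])
    return float(counts.max() / counts.sum())


def phase_classify(config: SurfaceConfiguration,
                   cutoff_pmpc: float | None = None,
                   cutoff_peo: float | None = None,
                   sigma_pmpc: float = 0.3, sigma_peo: float = 0.2) -> str:
    """Classify the surface pattern by largest-cluster connectivity.

    The discriminator is the largest-cluster mass fraction f of each
    species (fraction of that species' beads in its largest cluster):
    a species with f < 0.5 forms discrete domains, one with f >= 0.5
    percolates into a matrix.  Discrete domains of exactly one species
    give the micellar phase of that species (for PMPC this is the
    inverted phase); both percolating is bicontinuous; both fragmented
    is disordered; a single-species surface is uniform.

    Bead counts deliberately play no role: a triblock contributes one
    bead to each species, so at high triblock fractions the bead
    numbers are nearly equal and only connectivity distinguishes the
    matrix from the micelles.
    """
    kinds = config.kinds()
    n_peo = int(np.sum(kinds == KIND_PEO))
    n_pmpc = int(np.sum(kinds == KIND_PMPC))
    if n_peo == 0 or n_pmpc == 0:
        return "uniform"
    if cutoff_pmpc is None:
        cutoff_pmpc = _cutoff_for_kind(KIND_PMPC, sigma_pmpc, sigma_peo)
    if cutoff_peo is None:
        cutoff_peo = _cutoff_for_kind(KIND_PEO, sigma_pmpc, sigma_peo)
    f_peo = largest_cluster_fraction(config, KIND_PEO, cutoff_peo)
    f_pmpc = largest_cluster_fraction(config, KIND_PMPC, cutoff_pmpc)
    if f_peo >= 0.5 and f_pmpc >= 0.5:
        return "bicontinuous"
    if f_peo < 0.5 <= f_pmpc:
        return "micellar_PEO"
    if f_pmpc < 0.5 <= f_peo:
        return "micellar_PMPC"
    return "disordered"


def bead_nn_spacing(config: SurfaceConfiguration, kind: int | None = None
                    ) -> tuple[float, float]:
    """Mean and SD of per-bead nearest-neighbor geodesic distances.

    The baseline feature spacing of a single-species surface, where
    domain clustering is degenerate (everything connects).
    """
    if kind is None:
        pts = config.positions
    else:
        pts = config.positions[config.kinds() == kind]
    return nn_spacing(pts, metric="geodesic", radius=config.radius)
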