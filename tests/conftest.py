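import numpy as np
import pytest

from patchysome.params import ForceFieldParams, SpeciesMasses
from patchysome.sphere_init import SurfaceConfiguration, build_configuration


@pytest.fixture(scope="session")
def ff():
    return ForceFieldParams()


def random_surface_config(n, radius, rng, frac_peo=0.3, n_bonds=0):
    """Random beads on a sphere with random species; optional triblock bonds."""
    v = rng.standard_normal((n, 3))
    pos = radius * v / np.linalg.norm(v, axis=1, keepdims=True)
    species = np.where(rng.random(n) < frac_peo, 1, 0).astype(np.int64)
    bonds = np.empty((0, 2), np.int64)
    if n_bonds:
        idx = rng.choice(n, size=2 * n_bonds, replace=False)
        pairs = idx.reshape(-1, 2)
        species[pairs[:, 0]] = 2  # PMPC_tri
        species[pairs[:, 1]] = 3  # PEO_tri
        bonds = pairs.astype(np.int64)
    masses = SpeciesMasses()
    m = np.array([masses.for_species(s) for s in species])
    vel = rng.standard_normal((n, 3)) * 0.01
    unit = pos / radius
    vel -= np.sum(vel * unit, axis=1, keepdims=True) * unit
    return SurfaceConfiguration(radius=radius, positions=pos, species=species,
                                bonds=bonds, velocities=vel, masses=m, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    return build_configuration(n=400, radius=1.5, comp_frac_triblock=0.2, seed=42)
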