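import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from patchysome.domain_analysis import (InsufficientPointsError,
                                        UndefinedCenterError, analyze_domains,
                                        bead_nn_spacing, cluster_center,
                                        cluster_species, domain_size,
                                        nn_spacing, phase_classify)
from patchysome.params import KIND_PEO, KIND_PMPC
from patchysome.sphere_init import SurfaceConfiguration, fibonacci_lattice

from conftest import random_surface_config
from oracles import brute_force_nn_minima, union_find_clusters


def _config_from_points(points, species, radius=1.0):
    points = np.asarray(points, float)
    n = len(points)
    return SurfaceConfiguration(
        radius=radius, positions=points, species=np.asarray(species, np.int64),
        bonds=np.empty((0, 2), np.int64), velocities=np.zeros((n, 3)),
        masses=np.ones(n))


class TestClusterSpecies:
    def test_two_close_beads_one_cluster(self):
        pts = np.array([[0, 0, 1.0], [0, 0.09, 0.995]])
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        cfg = _config_from_points(pts, [0, 0])
        clusters = cluster_species(cfg, KIND_PMPC, cutoff=0.1)
        assert len(clusters) == 1

    def test_distant_beads_are_singletons(self):
        pts = fibonacci_lattice(20, 1.0)
        cfg = _config_from_points(pts, [0] * 20)
        clusters = cluster_species(cfg, KIND_PMPC, cutoff=0.01)
        assert len(clusters) == 20

    def test_absent_species_empty(self):
        cfg = _config_from_points([[0, 0, 1.0]], [0])
        assert cluster_species(cfg, KIND_PEO, cutoff=0.5) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cfg = random_surface_config(200, 1.0, rng, frac_peo=0.5)
        cutoff = 0.25
        ours = cluster_species(cfg, KIND_PEO, cutoff)
        ours_sorted = sorted(sorted(c.tolist()) for c in ours)
        idx = np.flatnonzero(cfg.kinds() == KIND_PEO)
        oracle_local = union_find_clusters(cfg.positions[idx], cutoff)
        oracle = sorted(sorted(idx[g].tolist()) for g in oracle_local)
        assert ours_sorted == oracle


class TestClusterCenter:
    def test_single_bead_center_is_itself(self):
        cfg = _config_from_points([[0, 0, 1.0]], [0])
        assert np.allclose(cluster_center(np.array([0]), cfg), [0, 0, 1.0])

    def test_symmetric_pair_centers_at_pole(self):
        pts = np.array([[0.1, 0, 0.99], [-0.1, 0, 0.99]])
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        cfg = _config_from_points(pts, [0, 0])
        c = cluster_center(np.array([0, 1]), cfg)
        assert np.allclose(c, [0, 0, 1.0], atol=1e-12)

    def test_antipodal_pair_is_undefined(self):
        cfg = _config_from_points([[0, 0, 1.0], [0, 0, -1.0]], [0, 0])
        with pytest.raises(UndefinedCenterError):
            cluster_center(np.array([0, 1]), cfg)


class TestNnSpacing:
    def test_equilateral_triangle(self):
        s = 2.0
        pts = np.array([[0, 0], [s, 0], [s / 2, s * np.sqrt(3) / 2]])
        mean, sd = nn_spacing(pts)
        assert mean == pytest.approx(s)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_collinear_hand_example(self):
        # points at 0, 1, 3: per-point minima {1, 1, 2}
        pts = np.array([[0.0, 0], [1.0, 0], [3.0, 0]])
        mean, sd = nn_spacing(pts)
        assert mean == pytest.approx(4.0 / 3.0)
        assert sd == pytest.approx(np.std([1, 1, 2], ddof=1))

    def test_single_point_raises(self):
        with pytest.raises(InsufficientPointsError):
            nn_spacing(np.array([[0.0, 0, 0]]))

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, (100, 3))
        mean, sd = nn_spacing(pts)
        minima = brute_force_nn_minima(pts)
        assert mean == pytest.approx(minima.mean(), rel=1e-12)
        assert sd == pytest.approx(minima.std(ddof=1), rel=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((50, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        m0, s0 = nn_spacing(pts, metric="geodesic", radius=1.0)
        rot = Rotation.random(random_state=1).as_matrix()
        m1, s1 = nn_spacing(pts @ rot.T, metric="geodesic", radius=1.0)
        assert m1 == pytest.approx(m0, rel=1e-10)
        assert s1 == pytest.approx(s0, rel=1e-10)

    def test_geodesic_exceeds_chord(self):
        pts = fibonacci_lattice(30, 1.0)
        chord_mean, _ = nn_spacing(pts, metric="euclidean")
        geo_mean, _ = nn_spacing(pts, metric="geodesic", radius=1.0)
        assert geo_mean > chord_mean


class TestDomainSize:
    def test_single_bead_arithmetic(self):
        # A = 4 pi R^2 / n for one bead of a 65539-bead 19.2-nm sphere
        pts = fibonacci_lattice(16, 19.2)
        cfg = _config_from_points(pts, [0] * 16, radius=19.2)
        cfg_n = cfg.n
        area = 4 * np.pi * 19.2 ** 2 / cfg_n
        expected = 2 * np.sqrt(area / np.pi)
        assert domain_size(np.array([0]), cfg) == pytest.approx(expected)

    def test_doubling_beads_scales_sqrt2(self):
        pts = fibonacci_lattice(64, 1.0)
        cfg = _config_from_points(pts, [0] * 64)
        d1 = domain_size(np.arange(4), cfg)
        d2 = domain_size(np.arange(8), cfg)
        assert d2 / d1 == pytest.approx(np.sqrt(2))

    def test_empty_cluster_raises(self):
        pts = fibonacci_lattice(8, 1.0)
        cfg = _config_from_points(pts, [0] * 8)
        with pytest.raises(ValueError):
            domain_size(np.array([], int), cfg)


class TestPhaseClassify:
    def test_single_species_uniform(self):
        pts = fibonacci_lattice(100, 1.0)
        cfg = _config_from_points(pts, [0] * 100)
        assert phase_classify(cfg) == "uniform"

    def test_compact_minority_patches_micellar(self):
        # 10 disjoint compact PEO patches in a PMPC matrix
        pts = fibonacci_lattice(400, 1.0)
        species = np.zeros(400, np.int64)
        anchors = fibonacci_lattice(10, 1.0)
        from scipy.spatial import cKDTree
        tree = cKDTree(pts)
        for a in anchors:
            _, members = tree.query(a, k=5)
            species[members] = 1
        cfg = _config_from_points(pts, species)
        assert phase_classify(cfg, cutoff_pmpc=0.3, cutoff_peo=0.12) == "micellar_PEO"

    def test_alternating_stripes_bicontinuous(self):
        pts = fibonacci_lattice(800, 1.0)
        # 4 broad latitude bands per species, each species' bands joined
        # through wide meridian seams on opposite sides
        z = pts[:, 2]
        band = np.floor((z + 1) * 4).astype(int) % 2
        species = band.astype(np.int64)
        phi = np.arctan2(pts[:, 1], pts[:, 0])
        species[np.abs(phi) < 0.3] = 1
        species[np.abs(np.abs(phi) - np.pi) < 0.3] = 0
        cfg = _config_from_points(pts, species)
        assert phase_classify(cfg, cutoff_pmpc=0.2, cutoff_peo=0.2) == "bicontinuous"

    def test_inverted_phase_with_majority_matrix(self):
        # discrete PMPC islands inside a connected PEO matrix must label
        # micellar_PMPC regardless of bead-count balance
        pts = fibonacci_lattice(400, 1.0)
        species = np.ones(400, np.int64)
        from scipy.spatial import cKDTree
        tree = cKDTree(pts)
        for a in fibonacci_lattice(8, 1.0):
            _, members = tree.query(a, k=6)
            species[members] = 0
        cfg = _config_from_points(pts, species)
        assert phase_classify(cfg, cutoff_pmpc=0.13, cutoff_peo=0.3) == "micellar_PMPC"


def test_bead_counts_conserved_in_analysis(small_config):
    ds = analyze_domains(small_config, KIND_PEO, cutoff=0.2)
    n_peo = int(np.sum(small_config.kinds() == KIND_PEO))
    assert sum(len(c) for c in ds.clusters) == n_peo


def test_bead_nn_spacing_matches_lattice(small_config):
    mean, sd = bead_nn_spacing(small_config)
    from patchysome.sphere_init import ideal_hex_spacing
    a_star = ideal_hex_spacing(small_config.n, small_config.radius)
    assert 0.7 * a_star < mean < 1.3 * a_star
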