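import numpy as np
import pytest

from patchysome.domain_analysis import InsufficientPointsError
from patchysome.image_spacing import (DomainCenters, measure_image_spacing,
                                      region_centers, segment_domains,
                                      spacing_from_centers)
from patchysome.synthetic_tem import (ProjectionImage, generate_point_pattern,
                                      render_projection)


def _blob_image(centers_px, size=96, amplitude=90, sigma=2.0, px_size=0.5):
    yy, xx = np.mgrid[0:size, 0:size]
    canvas = np.full((size, size), 128.0)
    for (r, c) in centers_px:
        canvas += amplitude * np.exp(-((yy - r) ** 2 + (xx - c) ** 2)
                                     / (2 * sigma ** 2))
    return ProjectionImage(pixels=np.clip(canvas, 0, 255).astype(np.uint8),
                           px_size=px_size)


class TestSegmentation:
    def test_uniform_image_no_regions(self):
        img = ProjectionImage(pixels=np.full((32, 32), 128, np.uint8),
                              px_size=0.5)
        labels, n = segment_domains(img, threshold=150, polarity="light")
        assert n == 0

    def test_disjoint_blobs_counted(self):
        centers = [(16, 16), (16, 48), (16, 80), (48, 16), (48, 48), (48, 80),
                   (80, 16), (80, 48), (80, 80)]
        img = _blob_image(centers)
        labels, n = segment_domains(img, threshold=170, polarity="light")
        assert n == len(centers)

    def test_min_area_filters_everything(self):
        img = _blob_image([(30, 30), (60, 60)])
        _, n = segment_domains(img, threshold=170, polarity="light",
                               min_area=10_000)
        assert n == 0

    def test_otsu_default_threshold(self):
        img = _blob_image([(30, 30), (60, 60)])
        _, n = segment_domains(img, polarity="light")
        assert n == 2


class TestCenters:
    def test_symmetric_blob_centered(self):
        img = _blob_image([(32, 32)], size=64)
        labels, n = segment_domains(img, threshold=170, polarity="light")
        centers = region_centers(img, labels, n, polarity="light")
        assert centers.points[0] == pytest.approx((32, 32), abs=0.1)

    def test_two_blobs_order_independent(self):
        img = _blob_image([(20, 20), (70, 70)])
        labels, n = segment_domains(img, threshold=170, polarity="light")
        centers = region_centers(img, labels, n, polarity="light")
        got = sorted(map(tuple, np.round(centers.points).astype(int)))
        assert got == [(20, 20), (70, 70)]


class TestSpacing:
    def test_pythagoras_hand_example(self):
        # centers (0,0), (3,4), (9,4): minima {5, 5, 6}
        centers = DomainCenters(points=np.array([[0, 0], [4, 3], [4, 9]], float),
                                px_to_nm=1.0)
        mean, sd = spacing_from_centers(centers)
        assert mean == pytest.approx(16.0 / 3.0)
        assert sd == pytest.approx(np.std([5, 5, 6], ddof=1))

    def test_two_centers(self):
        centers = DomainCenters(points=np.array([[0, 0], [0, 7]], float),
                                px_to_nm=1.0)
        mean, sd = spacing_from_centers(centers)
        assert mean == pytest.approx(7.0)
        assert sd == pytest.approx(0.0)

    def test_px_to_nm_linearity(self):
        pts = np.random.default_rng(0).uniform(0, 50, (20, 2))
        m1, s1 = spacing_from_centers(DomainCenters(points=pts, px_to_nm=1.0))
        m2, s2 = spacing_from_centers(DomainCenters(points=pts, px_to_nm=2.0))
        assert m2 == pytest.approx(2 * m1)
        assert s2 == pytest.approx(2 * s1)

    def test_translation_rotation_invariance(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 30, (25, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([5.0, -3.0])
        m0, s0 = spacing_from_centers(DomainCenters(points=pts, px_to_nm=1.0))
        m1, s1 = spacing_from_centers(DomainCenters(points=moved, px_to_nm=1.0))
        assert m1 == pytest.approx(m0, rel=1e-10)
        assert s1 == pytest.approx(s0, rel=1e-10)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientPointsError):
            spacing_from_centers(DomainCenters(points=np.zeros((1, 2)),
                                               px_to_nm=1.0))

    def test_matches_brute_force(self):
        from oracles import brute_force_nn_minima
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 100, (80, 2))
        mean, sd = spacing_from_centers(DomainCenters(points=pts, px_to_nm=0.5))
        minima = brute_force_nn_minima(pts) * 0.5
        assert mean == pytest.approx(minima.mean(), rel=1e-12)
        assert sd == pytest.approx(minima.std(ddof=1), rel=1e-12)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("spacing", [5.0, 6.5, 8.0])
    def test_hexagonal_fixture_recovered_within_5_percent(self, spacing):
        pts = generate_point_pattern("jittered_hex", spacing,
                                     jitter=0.1 * spacing,
                                     extent=(80, 80), seed=17)
        img = render_projection(pts, px_size=0.5, blur_sigma=0.8,
                                noise_sd=8.0, seed=17)
        from patchysome.domain_analysis import nn_spacing
        truth_mean, _ = nn_spacing(pts)
        stats = measure_image_spacing(img, polarity="light", min_area=4)
        assert stats["mean_nm"] == pytest.approx(truth_mean, rel=0.05)

    def test_centers_within_one_pixel_of_ground_truth(self):
        pts = generate_point_pattern("hexagonal", 7.0, 0.0, (42, 42), seed=3)
        # margin keeps footprints clear of the canvas border, where
        # clipping would bias the centroids inward
        pts = pts + 3.0
        img = render_projection(pts, px_size=0.5, blur_sigma=0.7,
                                noise_sd=0.0, extent=(48, 48))
        labels, n = segment_domains(img, polarity="light", min_area=4)
        centers = region_centers(img, labels, n, polarity="light")
        assert n == len(pts)
        # compare as sets: match each truth point to the nearest center
        got_nm = centers.points[:, ::-1] * img.px_size  # (row,col) -> (x,y)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(got_nm).query(pts)
        assert d.max() <= 1.0 * img.px_size
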