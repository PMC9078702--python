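"""AFS computation: closed-form intervals (s=2), traced polygons and the
grid oracle (s=3)."""

import numpy as np
import pytest
from scipy import ndimage
from shapely.geometry import Polygon

import mcrafs as m
from mcrafs.synthetic import gaussian_spectrum


@pytest.fixture(scope="module")
def two_component_svd():
    """Two overlapping Gaussian components without pure rows: genuine
    rotational ambiguity on both sides."""
    wl = np.linspace(200, 600, 201)
    S = np.column_stack(
        [
            gaussian_spectrum([(300, 40, 1.0)], wl),
            gaussian_spectrum([(430, 50, 0.8)], wl),
        ]
    )
    a = np.linspace(0.15, 0.85, 10)
    C = np.column_stack([1 - a, a]) * 1e-3
    ds = m.SpectralDataset(C @ S.T, wl, np.arange(10.0))
    return m.truncated_svd(ds, 2), S


class TestTwoComponent:
    def test_intervals_contain_true_coordinates(self, two_component_svd):
        svd, S = two_component_svd
        region = m.afs_two_component(svd, m.FeasibilityParams(epsilon=0.0))
        assert len(region.polygons) == 2
        hit = set()
        for i in range(2):
            x, _ = m.profile_to_afs_point(svd, S[:, i], "spectral")
            idx = region.contains(x)
            assert idx >= 0
            hit.add(idx)
        assert hit == {0, 1}

    def test_endpoints_match_brute_force_scan(self, two_component_svd):
        svd, _ = two_component_svd
        params = m.FeasibilityParams(epsilon=0.0, delta=1e-6)
        region = m.afs_two_component(svd, params)
        endpoints = np.sort(np.concatenate([p.ravel() for p in region.polygons]))
        lo, hi = endpoints[0] - 0.2, endpoints[-1] + 0.2
        xs = np.linspace(lo, hi, 2500)
        mask = np.array(
            [m.point_feasible(svd, [x], params).feasible for x in xs]
        )
        transitions = np.sort(xs[np.flatnonzero(np.diff(mask.astype(int)))])
        step = xs[1] - xs[0]
        assert transitions.size == 4
        assert np.max(np.abs(transitions - endpoints)) <= 2 * step

    def test_epsilon_enlarges_both_intervals(self, two_component_svd):
        svd, _ = two_component_svd
        r0 = m.afs_two_component(svd, m.FeasibilityParams(epsilon=0.0))
        r2 = m.afs_two_component(svd, m.FeasibilityParams(epsilon=2e-4))
        for p0, p2 in zip(r0.polygons, r2.polygons):
            assert p2.min() <= p0.min() + 1e-9
            assert p2.max() >= p0.max() - 1e-9

    def test_wrong_component_count_raises(self, small_svd):
        with pytest.raises(ValueError):
            m.afs_two_component(small_svd)


class TestPointFeasible:
    def test_true_spectra_are_feasible(self, small_synthetic, small_svd):
        _, _, S_true = small_synthetic
        for i in range(3):
            x, _ = m.profile_to_afs_point(small_svd, S_true[:, i], "spectral")
            assert m.point_feasible(small_svd, x).feasible

    def test_far_point_is_infeasible(self, small_svd):
        chk = m.point_feasible(small_svd, [1e3, 1e3])
        assert not chk.feasible
        assert chk.violation > 0

    def test_unsupported_dimension_raises(self):
        rng = np.random.default_rng(0)
        svd = m.truncated_svd(rng.uniform(size=(10, 20)), 4)
        with pytest.raises(NotImplementedError):
            m.point_feasible(svd, [0.0, 0.0, 0.0])


class TestThreeComponent:
    def test_three_isolated_subsets_with_truth_inside(
        self, small_synthetic, small_svd, small_region_default_eps
    ):
        region = small_region_default_eps
        _, _, S_true = small_synthetic
        assert len(region.polygons) == 3
        region._validate_geometry()  # simple + pairwise disjoint
        hit = set()
        for i in range(3):
            x, _ = m.profile_to_afs_point(small_svd, S_true[:, i], "spectral")
            idx = region.contains(x)
            assert idx >= 0, f"true component {i} outside every subset"
            hit.add(idx)
        assert hit == {0, 1, 2}

    def test_concentrational_side_matches_truth(self, small_synthetic, small_svd):
        _, C_true, _ = small_synthetic
        region = m.afs_three_component(
            small_svd, "concentrational", m.FeasibilityParams()
        )
        assert len(region.polygons) == 3
        hit = set()
        for i in range(3):
            y, _ = m.profile_to_afs_point(small_svd, C_true[:, i], "concentrational")
            idx = region.contains(y)
            assert idx >= 0
            hit.add(idx)
        assert hit == {0, 1, 2}

    def test_largest_subset_agrees_with_zoomed_grid_oracle(
        self, small_svd, small_region_default_eps
    ):
        region = small_region_default_eps
        params = region.params
        areas = [Polygon(p).area for p in region.polygons]
        big = int(np.argmax(areas))
        poly = region.polygons[big]
        pmn, pmx = poly.min(axis=0), poly.max(axis=0)
        pad = 0.2 * (pmx - pmn)
        bbox = (pmn[0] - pad[0], pmn[1] - pad[1], pmx[0] + pad[0], pmx[1] + pad[1])
        res = 48
        mask = m.afs_grid_oracle(small_svd, bbox, res, params)
        labels, nblobs = ndimage.label(mask)
        assert nblobs == 1
        xs = bbox[0] + (np.arange(res) + 0.5) * (bbox[2] - bbox[0]) / res
        ys = bbox[1] + (np.arange(res) + 0.5) * (bbox[3] - bbox[1]) / res
        XX, YY = np.meshgrid(xs, ys)
        import shapely

        inside = shapely.contains_xy(Polygon(poly), XX.ravel(), YY.ravel())
        diff = inside.reshape(res, res) ^ mask
        # any disagreeing cell center must sit in the boundary-precision
        # band of the traced polygon (pure grid discretization)
        assert int(diff.sum()) <= 6
        pg = Polygon(poly)
        for i, j in zip(*np.nonzero(diff)):
            from shapely.geometry import Point

            d = pg.exterior.distance(Point(xs[j], ys[i]))
            assert d <= 3 * params.eps_b

    def test_oracle_epsilon_monotone_pointwise(self, small_svd, small_region_default_eps):
        poly = max(small_region_default_eps.polygons, key=lambda p: Polygon(p).area)
        pmn, pmx = poly.min(axis=0), poly.max(axis=0)
        pad = 0.3 * (pmx - pmn)
        bbox = (pmn[0] - pad[0], pmn[1] - pad[1], pmx[0] + pad[0], pmx[1] + pad[1])
        m0 = m.afs_grid_oracle(small_svd, bbox, 24, m.FeasibilityParams(epsilon=0.0))
        m2 = m.afs_grid_oracle(small_svd, bbox, 24, m.FeasibilityParams(epsilon=2e-4))
        assert np.all(m2[m0])  # feasible at eps=0 stays feasible at eps=2e-4

    def test_far_bbox_oracle_is_all_infeasible(self, small_svd):
        mask = m.afs_grid_oracle(
            small_svd, (50.0, 50.0, 51.0, 51.0), 8, m.FeasibilityParams()
        )
        assert not mask.any()

    def test_resolution_guard(self, small_svd):
        with pytest.raises(ValueError):
            m.afs_grid_oracle(small_svd, (0, 0, 1, 1), 501)
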