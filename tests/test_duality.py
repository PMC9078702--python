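"""Duality between the factors: dual lines, intersections, completion."""

import numpy as np
import pytest

import mcrafs as m
from conftest import cosine
from mcrafs.duality import InconsistentConstraintsError


def conc_point_of_tinv_column(svd, Tinv, j):
    """Concentration-side AFS coordinates of column j of inv(T)."""
    a = svd.Sigma * Tinv[:, j]
    return a[1:] / a[0]


class TestDualLineIncidence:
    def test_complementary_columns_lie_on_the_line(self, small_svd):
        """The core duality theorem, instantiated numerically: for any
        regular T, the complementary components' concentration
        representations lie on the dual line of each spectral point."""
        rng = np.random.default_rng(20180312)
        worst = 0.0
        count = 0
        while count < 100:
            T = np.column_stack([np.ones(3), rng.normal(size=(3, 2))])
            if abs(np.linalg.det(T)) < 1e-3:
                continue
            count += 1
            Tinv = np.linalg.inv(T)
            for i in range(3):
                line = m.dual_line(T[i, 1:], small_svd)
                for j in range(3):
                    if j == i:
                        continue
                    y = conc_point_of_tinv_column(small_svd, Tinv, j)
                    worst = max(worst, abs(line.residual(y)))
        assert worst <= 1e-8

    def test_symmetry_concentrational_points_constrain_spectra(self, small_svd):
        """Swap test: the dual line of a concentrational point contains the
        complementary spectral points."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            T = np.column_stack([np.ones(3), rng.normal(size=(3, 2))])
            if abs(np.linalg.det(T)) < 1e-3:
                continue
            Tinv = np.linalg.inv(T)
            for j in range(3):
                y = conc_point_of_tinv_column(small_svd, Tinv, j)
                line = m.dual_line(y, small_svd)
                for i in range(3):
                    if i == j:
                        continue
                    assert abs(line.residual(T[i, 1:])) <= 1e-8


class TestIntersectLines:
    def test_axis_lines_cross_at_origin(self):
        a = m.DualLine(normal=[0.0, 1.0], offset=0.0)
        b = m.DualLine(normal=[1.0, 0.0], offset=0.0)
        assert np.allclose(m.intersect_lines(a, b), [0.0, 0.0])

    def test_hand_algebra(self):
        a = m.DualLine(normal=[1.0, 1.0], offset=-1.0)
        b = m.DualLine(normal=[1.0, -1.0], offset=0.0)
        assert np.allclose(m.intersect_lines(a, b), [0.5, 0.5])

    def test_parallel_lines_raise(self):
        a = m.DualLine(normal=[1.0, 2.0], offset=0.0)
        b = m.DualLine(normal=[2.0, 4.0], offset=1.0)
        with pytest.raises(ValueError, match="parallel"):
            m.intersect_lines(a, b)

    def test_two_fixed_spectra_pin_the_complementary_profile(
        self, small_synthetic, small_svd
    ):
        """Dual lines of the two endpoint spectra intersect at the true
        concentration point of the middle component."""
        _, C_true, S_true = small_synthetic
        xa, _ = m.profile_to_afs_point(small_svd, S_true[:, 0], "spectral")
        xb, _ = m.profile_to_afs_point(small_svd, S_true[:, 2], "spectral")
        y = m.intersect_lines(
            m.dual_line(xa, small_svd), m.dual_line(xb, small_svd)
        )
        y_true, _ = m.profile_to_afs_point(
            small_svd, C_true[:, 1], "concentrational"
        )
        assert np.linalg.norm(y - y_true) <= 1e-6


class TestProfileToAFSPoint:
    def test_leading_basis_vector_maps_to_origin(self, small_svd):
        x, res = m.profile_to_afs_point(small_svd, small_svd.V[:, 0], "spectral")
        assert np.allclose(x, 0.0, atol=1e-12)
        assert res <= 1e-12

    def test_data_row_lies_in_span(self, small_synthetic, small_svd):
        ds, _, _ = small_synthetic
        row = ds.absorbance[0]
        x, res = m.profile_to_afs_point(small_svd, row, "spectral")
        assert res <= 1e-10 * np.linalg.norm(row)
        assert m.point_feasible(small_svd, x).feasible

    def test_orthogonal_profile_raises(self, small_svd):
        # a vector orthogonal to the whole basis has zero leading coefficient
        n = small_svd.V.shape[0]
        rng = np.random.default_rng(0)
        v = rng.normal(size=n)
        v -= small_svd.V @ (small_svd.V.T @ v)
        with pytest.raises(ValueError, match="leading"):
            m.profile_to_afs_point(small_svd, v, "spectral")

    def test_length_mismatch_raises(self, small_svd):
        with pytest.raises(ValueError, match="length"):
            m.profile_to_afs_point(small_svd, np.ones(7), "spectral")


class TestCompleteFactorization:
    def test_two_plus_two_recovers_the_hidden_component(
        self, small_synthetic, small_svd
    ):
        _, C_true, S_true = small_synthetic
        pair = m.complete_factorization(
            small_svd,
            fixed_spectra=[S_true[:, 0], S_true[:, 2]],
            fixed_profiles=[C_true[:, 0], C_true[:, 2]],
        )
        assert pair.violation <= 1e-12
        assert 1 - cosine(pair.S[:, 2], S_true[:, 1]) <= 1e-8
        assert 1 - cosine(pair.C[:, 2], C_true[:, 1]) <= 1e-8

    def test_endpoint_rows_as_pure_spectra(self, small_synthetic, small_svd):
        """The titration workflow: first/last measured spectra are pure."""
        ds, C_true, S_true = small_synthetic
        pair = m.complete_factorization(
            small_svd,
            fixed_spectra=[ds.absorbance[0], ds.absorbance[-1]],
            fixed_profiles=[C_true[:, 0], C_true[:, 2]],
        )
        assert 1 - cosine(pair.S[:, 2], S_true[:, 1]) <= 1e-6

    def test_three_profiles_on_one_side(self, small_synthetic, small_svd):
        _, C_true, S_true = small_synthetic
        pair = m.complete_factorization(
            small_svd,
            fixed_profiles=[C_true[:, 0], C_true[:, 1], C_true[:, 2]],
        )
        for i in range(3):
            assert 1 - cosine(pair.S[:, i], S_true[:, i]) <= 1e-8

    def test_completion_is_feasible_at_eps_zero(self, small_synthetic, small_svd):
        _, C_true, S_true = small_synthetic
        pair = m.complete_factorization(
            small_svd,
            fixed_spectra=[S_true[:, 0], S_true[:, 2]],
            fixed_profiles=[C_true[:, 0], C_true[:, 2]],
            params=m.FeasibilityParams(epsilon=0.0),
        )
        assert pair.violation <= 1e-12

    def test_inconsistent_fixes_raise(self, small_svd):
        rng = np.random.default_rng(1)
        n = small_svd.V.shape[0]
        bogus = [np.abs(small_svd.V @ rng.normal(size=3)) + 0.1 for _ in range(3)]
        with pytest.raises((InconsistentConstraintsError, ValueError)):
            m.complete_factorization(small_svd, fixed_spectra=bogus)

    def test_insufficient_fixes_raise(self, small_svd, small_synthetic):
        _, _, S_true = small_synthetic
        with pytest.raises(ValueError, match="need"):
            m.complete_factorization(small_svd, fixed_spectra=[S_true[:, 0]])
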