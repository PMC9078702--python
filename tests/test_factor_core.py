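"""Factor model: truncated SVD, T parameterization, feasibility penalty."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mcrafs as m
from mcrafs.factor_core import INF_VIOLATION, _column_shortfalls


def random_nonneg_factorization(rng, k=15, n=40, s=3):
    C = rng.uniform(0.1, 1.0, size=(k, s))
    S = rng.uniform(0.0, 1.0, size=(n, s))
    return C, S, C @ S.T


class TestTruncatedSVD:
    def test_orthonormality_and_truncation_optimality(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            D = rng.normal(size=(12, 30))
            svd = m.truncated_svd(D, 4)
            assert np.allclose(svd.U.T @ svd.U, np.eye(4), atol=1e-10)
            assert np.allclose(svd.V.T @ svd.V, np.eye(4), atol=1e-10)
            assert np.all(np.diff(svd.all_singular_values) <= 1e-12)
            err = np.linalg.norm(D - svd.reconstruct())
            expected = np.sqrt(np.sum(svd.all_singular_values[4:] ** 2))
            assert err == pytest.approx(expected, rel=1e-8)

    def test_rank_one_input_has_zero_second_singular_value(self):
        rng = np.random.default_rng(1)
        D = np.outer(rng.uniform(1, 2, 10), rng.uniform(1, 2, 25))
        svd = m.truncated_svd(D, 2)
        assert svd.Sigma[1] <= 1e-12 * svd.Sigma[0]

    def test_exact_rank3_product_reconstructs(self):
        rng = np.random.default_rng(2)
        _, _, D = random_nonneg_factorization(rng)
        svd = m.truncated_svd(D, 3)
        assert np.linalg.norm(D - svd.reconstruct()) <= 1e-10 * np.linalg.norm(D)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(3)
        D = rng.normal(size=(8, 12))
        a = m.truncated_svd(D, 3)
        b = m.truncated_svd(D.copy(), 3)
        assert np.array_equal(a.V, b.V)
        for j in range(3):
            assert a.V[np.argmax(np.abs(a.V[:, j])), j] > 0

    def test_out_of_range_s_raises(self):
        D = np.eye(4)
        with pytest.raises(ValueError):
            m.truncated_svd(D, 0)
        with pytest.raises(ValueError):
            m.truncated_svd(D, 5)

    def test_transpose_svd_swaps_bases(self):
        rng = np.random.default_rng(4)
        D = rng.uniform(size=(9, 14))
        svd = m.truncated_svd(D, 3)
        tsvd = m.transpose_svd(svd)
        assert np.array_equal(tsvd.U, svd.V)
        assert np.array_equal(tsvd.V, svd.U)
        assert np.allclose(tsvd.reconstruct(), svd.reconstruct().T)


class TestEstimateRank:
    @pytest.mark.parametrize(
        "values, threshold, expected",
        [
            ((10, 5, 1, 1e-6), 1e-3, 3),
            ((1, 0, 0), 1e-3, 1),
            ((0, 0), 1e-3, 0),
            ((5, 4, 3, 2, 1), 0.5, 3),
        ],
    )
    def test_direct_definition(self, values, threshold, expected):
        assert m.estimate_rank(np.array(values, float), threshold) == expected

    def test_noiseless_synthetic_is_rank_three_for_any_sane_threshold(
        self, small_svd
    ):
        sv = small_svd.all_singular_values
        for thr in (1e-8, 1e-4, 0.9 * sv[2] / sv[0]):
            assert m.estimate_rank(sv, thr) == 3

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            m.estimate_rank(np.array([]))


class TestBuildT:
    def test_identity_completion(self):
        T = m.build_T([0.0, 0.0], np.eye(2))
        assert np.allclose(T.T[:, 0], 1.0)
        assert T.det() == pytest.approx(1.0)

    def test_two_component_determinant(self):
        T = m.build_T([0.3], [[1.7]])
        assert T.det() == pytest.approx(1.7 - 0.3)

    def test_equal_rows_are_singular(self):
        T = m.build_T([0.5, 0.2], [[0.5, 0.2], [0.5, 0.2]])
        assert not T.is_regular()

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            m.build_T([0.1, 0.2], np.eye(3))


class TestFactorsFromT:
    def test_random_regular_transform_reconstructs_truncation(self, small_svd):
        rng = np.random.default_rng(5)
        T = np.column_stack([np.ones(3), rng.normal(size=(3, 2))])
        pair = m.factors_from_T(small_svd, T)
        R = pair.C @ pair.S.T
        assert np.allclose(
            R, small_svd.reconstruct(), atol=1e-10 * small_svd.Sigma[0]
        )

    def test_true_factor_transform_recovers_ground_truth(self, small_synthetic, small_svd):
        _, C_true, S_true = small_synthetic
        pts = [
            m.profile_to_afs_point(small_svd, S_true[:, i], "spectral")[0]
            for i in range(3)
        ]
        T = np.column_stack([np.ones(3), np.array(pts)])
        pair = m.factors_from_T(small_svd, T)
        for i in range(3):
            ratio = pair.S[:, i] / S_true[:, i].max()
            truth = S_true[:, i] / S_true[:, i].max()
            scale = np.max(np.abs(ratio)) / np.max(np.abs(truth))
            assert np.allclose(ratio / scale, truth, atol=1e-6)

    def test_singular_transform_raises(self, small_svd):
        T = np.column_stack([np.ones(3), np.zeros((3, 2))])
        with pytest.raises(np.linalg.LinAlgError):
            m.factors_from_T(small_svd, T)


def _fabricated_svd(C, S, T):
    """A TruncatedSVDResult whose US/V reproduce given factors under T."""
    Tinv = np.linalg.inv(T)
    US = C @ T  # so that US @ inv(T) == C
    V = S @ Tinv.T  # so that V @ T.T == S
    s = T.shape[0]
    return m.TruncatedSVDResult(
        U=US, Sigma=np.ones(s), V=V, all_singular_values=np.ones(s), s=s
    )


class TestFeasibilityViolation:
    def test_exact_nonnegative_factorization_scores_zero(self, small_svd, small_synthetic):
        _, C_true, S_true = small_synthetic
        pts = [
            m.profile_to_afs_point(small_svd, S_true[:, i], "spectral")[0]
            for i in range(3)
        ]
        T = np.column_stack([np.ones(3), np.array(pts)])
        v = m.feasibility_violation(small_svd, T, m.FeasibilityParams(epsilon=1e-6))
        assert v <= 1e-12

    def test_single_negative_entry_formula(self):
        # S column 1 has one entry -0.01 against a maximum of 1
        T = np.column_stack([np.ones(2), [0.0, 1.0]])
        C = np.ones((4, 2))
        S = np.array([[1.0, 1.0], [0.5, 0.2], [-0.01, 0.3], [0.2, 0.9]])
        svd = _fabricated_svd(C, S, T)
        v0 = m.feasibility_violation(svd, T, m.FeasibilityParams(epsilon=0.0))
        assert v0 == pytest.approx(1e-4, rel=1e-12)
        v2 = m.feasibility_violation(svd, T, m.FeasibilityParams(epsilon=2e-2))
        assert v2 == 0.0

    def test_singular_transform_yields_infinite_sentinel(self, small_svd):
        T = np.column_stack([np.ones(3), np.zeros((3, 2))])
        assert m.feasibility_violation(small_svd, T) == INF_VIOLATION

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_scale_invariance_of_shortfalls(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(12, 3))
        scales = rng.uniform(0.1, 10.0, size=3)
        a = _column_shortfalls(M, 1e-3)
        b = _column_shortfalls(M * scales, 1e-3)
        assert np.allclose(a, b, rtol=1e-12)

    def test_compiled_kernel_matches_reference(self, small_svd):
        from mcrafs._kernels import violation3

        rng = np.random.default_rng(7)
        US = np.ascontiguousarray(small_svd.US)
        V = np.ascontiguousarray(small_svd.V)
        for _ in range(25):
            x = rng.normal(scale=1.5, size=2)
            W = rng.normal(scale=1.5, size=(2, 2))
            ref = m.feasibility_violation(
                small_svd, m.build_T(x, W), m.FeasibilityParams(epsilon=2e-4)
            )
            fast = violation3(
                x[0], x[1], W[0, 0], W[0, 1], W[1, 0], W[1, 1], US, V, 2e-4
            )
            if np.isinf(ref):
                assert fast >= 1e299
            else:
                assert fast == pytest.approx(ref, rel=1e-10, abs=1e-14)
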