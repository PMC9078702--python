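"""Truncated-SVD factor model and the T-matrix parameterization.

A mixture-spectra matrix ``D`` (k conditions x n channels) with ``s``
absorbing components factorizes, by Lambert-Beer, as ``D = C @ S.T`` with
nonnegative concentration profiles ``C`` (k x s) and pure spectra ``S``
(n x s).  Every rank-``s`` factorization can be written over the truncated
SVD ``D = U @ diag(Sigma) @ V.T`` as::

    C = U @ diag(Sigma) @ inv(T),      S = V @ T.T

for a regular s x s transform ``T`` whose first column is normalized to the
all-ones vector.  Rotational ambiguity is then the set of admissible ``T``;
everything downstream (AFS computation, duality, bands) lives in this
parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import SpectralDataset

__all__ = [
    "TruncatedSVDResult",
    "TransformMatrix",
    "FactorPair",
    "FeasibilityParams",
    "SingularTransformError",
    "truncated_svd",
    "transpose_svd",
    "estimate_rank",
    "build_T",
    "factors_from_T",
    "feasibility_violation",
]

#: sentinel returned by :func:`feasibility_violation` for singular transforms
INF_VIOLATION = np.inf

#: relative determinant threshold below which a transform counts as singular
DET_RTOL = 1e-12


class SingularTransformError(np.linalg.LinAlgError):
    """The transform matrix T is (numerically) singular."""


@dataclass
class TruncatedSVDResult:
    """Rank-``s`` truncated SVD of a dataset, plus the full singular spectrum.

    ``U`` (k x s) and ``V`` (n x s) have orthonormal columns, ``Sigma`` holds
    the s leading singular values, and ``all_singular_values`` the complete
    nonincreasing spectrum for rank diagnostics.  Each right singular vector
    is oriented so that its largest-magnitude entry is positive, which makes
    AFS coordinates reproducible across platforms; the corresponding left
    vector carries the compensating sign.
    """

    U: np.ndarray
    Sigma: np.ndarray
    V: np.ndarray
    all_singular_values: np.ndarray
    s: int

    @property
    def US(self) -> np.ndarray:
        """``U @ diag(Sigma)`` — the concentration-side basis (k x s)."""
        return self.U * self.Sigma[np.newaxis, :]

    def reconstruct(self) -> np.ndarray:
        """The optimal rank-``s`` approximation ``U @ diag(Sigma) @ V.T``."""
        return self.US @ self.V.T


@dataclass
class TransformMatrix:
    """The s x s basis transform ``T`` with all-ones first column.

    ``x = T[0, 1:]`` is the AFS point of the first spectrum and
    ``W = T[1:, 1:]`` the completion block.
    """

    T: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        s = self.T.shape[0]
        if self.T.shape != (s, s):
            raise ValueError("T must be square")
        if not np.allclose(self.T[:, 0], 1.0, rtol=0, atol=1e-12):
            raise ValueError("first column of T must be the all-ones vector")

    @property
    def s(self) -> int:
        return self.T.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.T[0, 1:]

    @property
    def W(self) -> np.ndarray:
        return self.T[1:, 1:]

    def det(self) -> float:
        return float(np.linalg.det(self.T))

    def is_regular(self) -> bool:
        scale = np.max(np.abs(self.T))
        return abs(self.det()) > DET_RTOL * max(scale, 1.0) ** self.s


@dataclass
class FactorPair:
    """A concentration/spectra factor pair ``D ~= C @ S.T``.

    ``violation`` (if set) is the feasibility penalty of the pair, see
    :func:`feasibility_violation`; 0 means the pair is nonnegative within
    the epsilon tolerance it was checked with.
    """

    C: np.ndarray
    S: np.ndarray
    violation: float | None = None
    labels: list | None = None


@dataclass
class FeasibilityParams:
    """Control parameters of the relaxed nonnegativity test.

    epsilon
        Acceptance bound on the relative magnitude of negative entries of a
        profile: a column ``v`` passes when ``min(v) >= -epsilon * max|v|``.
    delta
        Tolerance of the inner completion search: a point counts feasible
        when the minimized violation is ``<= delta**2``.
    eps_b
        Boundary precision of traced AFS polygons, in AFS coordinate units.
    """

    epsilon: float = 2e-4
    delta: float = 1e-4
    eps_b: float = 1e-4

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.delta <= 0 or self.eps_b <= 0:
            raise ValueError("delta and eps_b must be > 0")


def truncated_svd(dataset: SpectralDataset | np.ndarray, s: int) -> TruncatedSVDResult:
    """Rank-``s`` truncated SVD of the absorbance matrix.

    Accepts either a :class:`SpectralDataset` or a plain matrix.  The full
    singular spectrum is retained in ``all_singular_values``.
    """
    D = dataset.absorbance if isinstance(dataset, SpectralDataset) else np.asarray(dataset, float)
    k, n = D.shape
    if not 1 <= s <= min(k, n):
        raise ValueError(f"s={s} out of range for a {k}x{n} matrix")
    U, sv, Vt = np.linalg.svd(D, full_matrices=False)
    V = Vt.T
    # orientation: largest-magnitude entry of each right singular vector > 0
    for j in range(min(k, n)):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    return TruncatedSVDResult(
        U=U[:, :s].copy(),
        Sigma=sv[:s].copy(),
        V=V[:, :s].copy(),
        all_singular_values=sv.copy(),
        s=s,
    )


def transpose_svd(svd: TruncatedSVDResult) -> TruncatedSVDResult:
    """The SVD of the transposed matrix, reusing the same singular vectors.

    ``D.T = V @ diag(Sigma) @ U.T``; swapping the roles of U and V (rather
    than recomputing an SVD) keeps the sign conventions of both sides
    mutually consistent, which the duality machinery relies on.
    """
    return TruncatedSVDResult(
        U=svd.V.copy(),
        Sigma=svd.Sigma.copy(),
        V=svd.U.copy(),
        all_singular_values=svd.all_singular_values.copy(),
        s=svd.s,
    )


def estimate_rank(all_singular_values: np.ndarray, ratio_threshold: float = 1e-2) -> int:
    """Number of dominant singular values.

    Returns the largest ``s`` with ``sigma_s / sigma_1 >= ratio_threshold``,
    or 0 for an all-zero spectrum.  The default threshold of 1e-2 separates
    chemical rank from the noise floor for data with a signal-to-noise ratio
    of roughly a thousand, as typical for preprocessed UV/Vis absorbance.
    """
    sv = np.asarray(all_singular_values, dtype=float)
    if sv.size == 0:
        raise ValueError("empty singular value vector")
    if not 0 < ratio_threshold < 1:
        raise ValueError("ratio_threshold must be in (0, 1)")
    if sv[0] <= 0:
        return 0
    return int(np.sum(sv / sv[0] >= ratio_threshold))


def build_T(x: np.ndarray, W: np.ndarray) -> TransformMatrix:
    """Assemble ``T`` from the first-row tail ``x`` and the completion ``W``.

    ``T = [[1, x], [1, W]]`` with the all-ones first column.  Regularity is
    not checked here; use sites decide how to treat singular transforms.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    W = np.atleast_2d(np.asarray(W, dtype=float))
    m = x.size
    if W.shape != (m, m):
        raise ValueError(f"W must be {m}x{m} to match x of length {m}")
    s = m + 1
    T = np.empty((s, s))
    T[:, 0] = 1.0
    T[0, 1:] = x
    T[1:, 1:] = W
    return TransformMatrix(T)


def factors_from_T(svd: TruncatedSVDResult, T: TransformMatrix | np.ndarray) -> FactorPair:
    """Reconstruct ``(C, S)`` from a regular transform.

    ``C = U Sigma T^-1`` and ``S = V T.T``; raises
    :class:`SingularTransformError` for singular ``T``.  No nonnegativity is
    implied — use :func:`feasibility_violation` to test it.
    """
    if not isinstance(T, TransformMatrix):
        T = TransformMatrix(np.asarray(T, dtype=float))
    if T.s != svd.s:
        raise ValueError(f"T is {T.s}x{T.s} but the SVD has s={svd.s}")
    if not T.is_regular():
        raise SingularTransformError("transform matrix T is singular")
    C = svd.US @ np.linalg.inv(T.T)
    S = svd.V @ T.T.T
    return FactorPair(C=C, S=S)


def _column_shortfalls(M: np.ndarray, epsilon: float) -> np.ndarray:
    """Per-column relative-negativity shortfalls of a factor matrix."""
    mn = M.min(axis=0)
    mx = np.abs(M).max(axis=0)
    mx = np.where(mx > 0, mx, 1.0)  # all-zero column: no negative entries
    return np.maximum(0.0, -mn / mx - epsilon)


def feasibility_violation(
    svd: TruncatedSVDResult,
    T: TransformMatrix | np.ndarray,
    params: FeasibilityParams | None = None,
) -> float:
    """Penalty for negative entries of the factors generated by ``T``.

    For each component profile (each column of C and of S) the shortfall is
    ``max(0, -min/max_abs - epsilon)``, i.e. how far the most negative entry
    undercuts the accepted relative negativity ``epsilon``; the violation is
    the sum of squared shortfalls.  The per-profile normalization by the
    profile's own max-abs entry makes the measure invariant under the
    intrinsic column rescaling of the factorization.  A singular ``T``
    yields ``inf`` so optimizers can penalize it smoothly instead of raising.
    """
    if params is None:
        params = FeasibilityParams()
    if not isinstance(T, TransformMatrix):
        T = TransformMatrix(np.asarray(T, dtype=float))
    if not np.all(np.isfinite(T.T)):
        return INF_VIOLATION
    if not T.is_regular():
        return INF_VIOLATION
    C = svd.US @ np.linalg.inv(T.T)
    S = svd.V @ T.T.T
    eps = params.epsilon
    short = np.concatenate([_column_shortfalls(C, eps), _column_shortfalls(S, eps)])
    return float(np.dot(short, short))
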