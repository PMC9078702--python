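"""Duality (complementarity) between the concentration and spectral factors.

Because ``inv(T) @ T = I``, a known row of ``T`` (a fixed spectrum) imposes
an affine constraint on the complementary columns of ``inv(T)`` — and hence
on the complementary concentration profiles.  For a three-component system
the constraint is a straight line in the complementary AFS plane: fixing a
spectrum draws a line in the concentrational AFS on which the two remaining
components must lie, and vice versa.  Intersecting the lines of two fixed
profiles pins the complementary component uniquely (up to positive scale).

With AFS points normalized as expansion coefficients in the singular-vector
bases (Sigma omitted from the plot coordinates, the convention used
throughout this package), the dual line of a point ``x`` is::

    1 + (s1/s2) * x1 * y1 + (s1/s3) * x2 * y2 = 0

where ``s1 >= s2 >= s3`` are the singular values.  The form is symmetric in
the two factor sides, and is verified numerically against explicit
``inv(T)`` algebra in the test suite rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .factor_core import (
    FactorPair,
    FeasibilityParams,
    TruncatedSVDResult,
    feasibility_violation,
    transpose_svd,
)

__all__ = [
    "DualLine",
    "InconsistentConstraintsError",
    "profile_to_afs_point",
    "dual_line",
    "intersect_lines",
    "complete_factorization",
]


class InconsistentConstraintsError(ValueError):
    """Fixed profiles/spectra contradict each other beyond tolerance."""

    def __init__(self, message: str, violation: float):
        super().__init__(message)
        self.violation = violation


@dataclass
class DualLine:
    """The line ``{y : normal . y + offset = 0}`` in an AFS plane."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        if np.linalg.norm(self.normal) == 0:
            raise ValueError("dual line normal must be nonzero")

    def residual(self, y) -> float:
        """Signed incidence residual of a point, scaled by the normal."""
        y = np.asarray(y, dtype=float)
        return float((self.normal @ y + self.offset) / np.linalg.norm(self.normal))


def profile_to_afs_point(
    svd: TruncatedSVDResult, profile: np.ndarray, side: str = "spectral"
):
    """AFS coordinates of a measured profile, plus its projection residual.

    The profile is expanded in the ``s`` leading singular vectors of its
    side (least squares; the bases are orthonormal so the coefficients are
    plain inner products) and normalized to leading coefficient 1.

    Returns ``(point, residual_norm)`` where ``point`` has length ``s - 1``.
    Raises for profiles (near-)orthogonal to the leading singular vector,
    which cannot be normalized.
    """
    profile = np.asarray(profile, dtype=float).ravel()
    basis = svd.V if side == "spectral" else svd.U
    if profile.size != basis.shape[0]:
        raise ValueError(
            f"profile length {profile.size} does not match the {side} basis "
            f"({basis.shape[0]})"
        )
    coeffs = basis.T @ profile
    residual = float(np.linalg.norm(profile - basis @ coeffs))
    if abs(coeffs[0]) < 1e-10 * max(np.linalg.norm(profile), 1e-300):
        raise ValueError("leading expansion coefficient is (near) zero")
    return coeffs[1:] / coeffs[0], residual


def dual_line(point, svd: TruncatedSVDResult) -> DualLine:
    """Dual line of an AFS point, in the complementary AFS plane (s = 3).

    The same formula serves both directions (spectral point -> line in the
    concentrational AFS, and vice versa) because the underlying bilinear
    incidence form is symmetric.
    """
    if svd.s != 3:
        raise ValueError("dual lines are defined for three-component systems")
    point = np.asarray(point, dtype=float).ravel()
    if point.size != 2 or not np.all(np.isfinite(point)):
        raise ValueError("need a finite 2-vector AFS point")
    s1, s2, s3 = svd.Sigma
    normal = np.array([point[0] * s1 / s2, point[1] * s1 / s3])
    return DualLine(normal=normal, offset=1.0)


def intersect_lines(a: DualLine, b: DualLine) -> np.ndarray:
    """Intersection point of two dual lines; raises for (near-)parallel lines."""
    cross = a.normal[0] * b.normal[1] - a.normal[1] * b.normal[0]
    scale = np.linalg.norm(a.normal) * np.linalg.norm(b.normal)
    if abs(cross) <= 1e-12 * scale:
        raise ValueError("dual lines are parallel; no unique intersection")
    A = np.vstack([a.normal, b.normal])
    rhs = -np.array([a.offset, b.offset])
    return np.linalg.solve(A, rhs)


def complete_factorization(
    svd: TruncatedSVDResult,
    fixed_spectra=(),
    fixed_profiles=(),
    params: FeasibilityParams | None = None,
) -> FactorPair:
    """Build a full factorization from fixed spectra and/or profiles (s = 3).

    Supported input patterns:

    * three fixed spectra, or three fixed profiles;
    * two fixed spectra plus two fixed profiles of the same two components
      (the standard titration workflow: endpoint spectra plus two measured
      concentration profiles) — each pair of dual lines pins the missing
      point on the other side.

    The result is unique up to positive column scaling (spectra are
    normalized to unit maximum) and component permutation (components are
    ordered: fixed spectra first, duality-derived component last).  Raises
    :class:`InconsistentConstraintsError` when the fixes contradict each
    other (feasibility violation above ``100 * delta**2``).
    """
    params = params or FeasibilityParams()
    if svd.s != 3:
        raise ValueError("complete_factorization requires s = 3")
    spec_pts = [profile_to_afs_point(svd, p, "spectral")[0] for p in fixed_spectra]
    conc_pts = [
        profile_to_afs_point(svd, p, "concentrational")[0] for p in fixed_profiles
    ]

    if len(spec_pts) >= 3:
        rows = spec_pts[:3]
    elif len(conc_pts) >= 3:
        # a concentrational point of D is a spectral point of D-transposed,
        # so build the transform on the transposed problem and swap factors
        tsvd = transpose_svd(svd)
        Tc = np.column_stack([np.ones(3), np.array(conc_pts[:3])])
        pair = _pair_from_T(tsvd, Tc, params)
        C, S = _unit_max_spectra(pair.S, pair.C)
        return FactorPair(C=C, S=S, violation=pair.violation)
    elif len(spec_pts) == 2 and len(conc_pts) >= 2:
        la = dual_line(conc_pts[0], svd)
        lb = dual_line(conc_pts[1], svd)
        third = intersect_lines(la, lb)
        rows = [spec_pts[0], spec_pts[1], third]
    else:
        raise ValueError(
            "need three fixes on one side, or two spectra plus two profiles"
        )

    T = np.column_stack([np.ones(3), np.array(rows)])
    return _pair_from_T(svd, T, params)


def _pair_from_T(svd, T, params) -> FactorPair:
    viol = feasibility_violation(svd, T, params)
    if not np.isfinite(viol):
        raise InconsistentConstraintsError(
            "fixed profiles lead to a singular transform", float(viol)
        )
    if viol > 100.0 * params.delta**2:
        raise InconsistentConstraintsError(
            f"fixed profiles are mutually inconsistent (violation {viol:.3e})",
            float(viol),
        )
    C = svd.US @ np.linalg.inv(T)
    S = svd.V @ T.T
    C, S = _unit_max_spectra(C, S)
    return FactorPair(C=C, S=S, violation=float(viol))


def _unit_max_spectra(C, S):
    """Scale convention: unit-maximum spectra, concentrations absorb the scale."""
    smax = np.max(np.abs(S), axis=0)
    smax = np.where(smax > 0, smax, 1.0)
    sgn = np.sign(S[np.argmax(np.abs(S), axis=0), np.arange(S.shape[1])])
    sgn = np.where(sgn == 0, 1.0, sgn)
    return C * (smax * sgn), S / (smax * sgn)
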