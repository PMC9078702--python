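"""Feasible-profile bands and closure (mass-balance) scaling.

The rotational ambiguity summarized by an AFS subset can be re-expressed in
profile space: sampling points of the subset and reconstructing the
corresponding profiles yields a *band* whose pointwise envelope visualizes
how much of the profile is actually determined by the data.

The closure constraint ``sum_i w_i c_i(a) = c0`` (stoichiometric mass
balance) fixes the absolute scale of concentration profiles that the
bilinear model leaves free; :func:`closure_scale` computes the per-column
scale factors in the least-squares sense along the whole titration axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point as _ShPoint
from shapely.geometry import Polygon as _ShPolygon

from .afs import CONCENTRATIONAL, AFSRegion
from .factor_core import TruncatedSVDResult, transpose_svd

__all__ = [
    "BandEnvelope",
    "ClosureSpec",
    "band_envelopes",
    "closure_scale",
    "closure_ssq",
    "ScalingError",
    "EmptyRegionError",
]


class ScalingError(RuntimeError):
    """No positive closure scaling exists."""


class EmptyRegionError(ValueError):
    """The requested AFS subset is empty."""


@dataclass
class BandEnvelope:
    """Pointwise min/max envelope of the feasible profiles of one component."""

    axis: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    component: int
    n_samples: int

    def width(self) -> float:
        return float(np.max(self.upper - self.lower))

    def contains(self, profile: np.ndarray, tol: float = 1e-8) -> bool:
        profile = np.asarray(profile, dtype=float)
        scale = max(np.max(np.abs(self.upper)), 1e-300)
        return bool(
            np.all(profile >= self.lower - tol * scale)
            and np.all(profile <= self.upper + tol * scale)
        )


@dataclass
class ClosureSpec:
    """Stoichiometric closure ``sum_i weights[i] * c_i = c0``."""

    weights: np.ndarray
    c0: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if np.any(self.weights <= 0):
            raise ValueError("closure weights must be positive")
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")


def _profile_of_point(svd: TruncatedSVDResult, x) -> np.ndarray:
    """The profile represented by an AFS point, normalized to unit maximum."""
    prof = svd.V[:, 0] + svd.V[:, 1:] @ np.asarray(x, dtype=float)
    mx = np.max(np.abs(prof))
    return prof / mx if mx > 0 else prof


def band_envelopes(
    svd: TruncatedSVDResult,
    region: AFSRegion,
    component: int,
    n_samples: int = 200,
    seed: int = 0,
) -> BandEnvelope:
    """Band of feasible profiles for one AFS subset.

    Samples the subset (all boundary vertices plus seeded rejection-sampled
    interior points, so envelope extremes are never sampling-limited at the
    boundary), reconstructs each point's profile normalized to unit
    maximum, and returns the pointwise envelopes.  ``svd`` is always the
    SVD of the data matrix ``D``; for a concentrational region the
    transposed problem is used internally.
    """
    work = transpose_svd(svd) if region.factor_side == CONCENTRATIONAL else svd
    try:
        poly = region.polygons[component]
    except IndexError:
        raise EmptyRegionError(f"region has no component {component}") from None
    if poly.size == 0:
        raise EmptyRegionError(f"component {component} subset is empty")

    pts = [v for v in poly]
    if poly.shape[0] >= 3 and poly.shape[1] == 2:
        sh = _ShPolygon(poly)
        if sh.is_valid and sh.area > 0:
            rng = np.random.default_rng(seed)
            minx, miny, maxx, maxy = sh.bounds
            want = max(0, n_samples - len(pts))
            tries = 0
            while want > 0 and tries < 200 * n_samples:
                p = rng.uniform((minx, miny), (maxx, maxy))
                tries += 1
                if sh.contains(_ShPoint(p)):
                    pts.append(p)
                    want -= 1
    profiles = np.array([_profile_of_point(work, p) for p in pts])
    axis = np.arange(profiles.shape[1], dtype=float)
    return BandEnvelope(
        axis=axis,
        lower=profiles.min(axis=0),
        upper=profiles.max(axis=0),
        component=component,
        n_samples=len(pts),
    )


def closure_scale(C: np.ndarray, spec: ClosureSpec):
    """Positive column scales enforcing the closure in least squares.

    Finds ``gamma > 0`` minimizing ``sum_j (sum_i w_i gamma_i C[j,i] - c0)^2``
    and returns ``(C * gamma, gamma)``.  When the design matrix is
    ill-conditioned (condition number > 1e6) the scale of some component is
    not determined by the closure; the minimum-norm positive solution is
    returned and ``gamma_ambiguous`` is flagged via a warning attribute on
    the result (a third return value).
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[1] != spec.weights.size:
        raise ValueError("C must be (k, s) matching the closure weights")
    if np.any(np.max(np.abs(C), axis=0) == 0):
        raise ScalingError("a concentration column is identically zero")
    A = C * spec.weights[np.newaxis, :]
    rhs = np.full(C.shape[0], spec.c0)
    cond = np.linalg.cond(A)
    ambiguous = bool(cond > 1e6)
    gamma, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    if np.any(gamma <= 0):
        from scipy.optimize import nnls

        gamma, _ = nnls(A, rhs)
        if np.any(gamma <= 0):
            raise ScalingError(
                "no positive closure scaling exists for these profiles"
            )
    return C * gamma[np.newaxis, :], gamma, ambiguous


def closure_ssq(C: np.ndarray, spec: ClosureSpec) -> float:
    """Squared-error sum of the closure over the titration points.

    ``sum_j (sum_i weights[i] * C[j, i] - c0)^2``.
    """
    C = np.asarray(C, dtype=float)
    dev = C @ spec.weights - spec.c0
    return float(dev @ dev)
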