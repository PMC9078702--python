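"""Area of feasible solutions (AFS) computation.

A point ``x`` in the (s-1)-dimensional AFS of the spectral factor represents
the spectrum ``V[:,0] + x[0]*V[:,1] + ... `` (expansion coefficients in the
right singular basis, normalized to leading coefficient 1).  The point is
*feasible* when some completion ``W`` of the transform ``T = [[1, x], [1, W]]``
makes every column of both factors nonnegative up to the relative tolerance
``epsilon``.  The concentrational AFS is the same construction applied to
the transposed data matrix (left singular basis), with mutually consistent
sign conventions (see :func:`mcrafs.factor_core.transpose_svd`).

For s = 2 the AFS consists of two closed intervals available in closed form
(the classic two-component self-modeling bounds); for s = 3 each of the up
to three subsets is traced as a polygon by radial bisection from an interior
seed, refined adaptively until the polygon chords follow the true boundary.
A brute-force grid oracle is provided for testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point as _ShPoint
from shapely.geometry import Polygon as _ShPolygon
from shapely.geometry import box as _sh_box

from ._kernels import BIG, min_violation3, violation3
from .factor_core import (
    FeasibilityParams,
    TransformMatrix,
    TruncatedSVDResult,
    build_T,
    feasibility_violation,
    transpose_svd,
)

__all__ = [
    "AFSRegion",
    "FeasibilityCheck",
    "point_feasible",
    "afs_two_component",
    "afs_three_component",
    "afs_grid_oracle",
    "SeedingError",
]

SPECTRAL = "spectral"
CONCENTRATIONAL = "concentrational"

#: number of random completion starts in the multi-start search
N_RANDOM_STARTS = 8
#: fixed seed of the random-start stream (same starts for every point)
_START_SEED = 20180312
_NM_MAXITER = 160


class SeedingError(RuntimeError):
    """Fewer feasible seed points were found than components requested."""


@dataclass
class FeasibilityCheck:
    """Outcome of a point-feasibility test."""

    feasible: bool
    violation: float
    W: np.ndarray | None = None

    def __bool__(self) -> bool:
        return self.feasible


@dataclass
class AFSRegion:
    """One or more disjoint feasible subsets of an AFS.

    ``polygons`` is a list of ``(m, s-1)`` vertex arrays: closed polygons
    (implicit closure, counterclockwise) for s = 3, two-point intervals for
    s = 2.
    """

    factor_side: str
    polygons: list
    params: FeasibilityParams
    component_labels: list | None = None
    validate: bool = True

    def __post_init__(self) -> None:
        self.polygons = [np.atleast_2d(np.asarray(p, dtype=float)) for p in self.polygons]
        if self.factor_side not in (SPECTRAL, CONCENTRATIONAL):
            raise ValueError(f"unknown factor side {self.factor_side!r}")
        if self.validate:
            self._validate_geometry()

    def _validate_geometry(self) -> None:
        dims = {p.shape[1] for p in self.polygons}
        if len(dims) > 1:
            raise ValueError("mixed AFS dimensions in one region")
        if dims == {1}:
            for p in self.polygons:
                lo, hi = p.min(), p.max()
                if not lo <= hi:  # pragma: no cover - defensive
                    raise ValueError("invalid interval")
            return
        shapes = [pg for pg in self.shapely_polygons() if pg is not None]
        for pg in shapes:
            if not pg.is_valid:
                raise ValueError("self-intersecting AFS polygon")
        for i in range(len(shapes)):
            for j in range(i + 1, len(shapes)):
                if shapes[i].intersects(shapes[j]):
                    raise ValueError("AFS polygons are not pairwise disjoint")

    def shapely_polygons(self) -> list:
        """Shapely polygons (2-D regions only; degenerate ones become buffered points)."""
        out = []
        for p in self.polygons:
            if p.shape[1] != 2:
                out.append(None)
            elif p.shape[0] >= 3:
                pg = _ShPolygon(p)
                if not pg.is_valid:
                    pg = pg.buffer(0)
                out.append(pg)
            else:
                out.append(_ShPoint(p.mean(axis=0)).buffer(1e-12))
        return out

    def contains(self, x) -> int:
        """Index of the subset containing ``x`` (within eps_b), or -1."""
        x = np.asarray(x, dtype=float)
        tol = self.params.eps_b
        if self.polygons and self.polygons[0].shape[1] == 1:
            for i, p in enumerate(self.polygons):
                if p.min() - tol <= x[0] <= p.max() + tol:
                    return i
            return -1
        for i, pg in enumerate(self.shapely_polygons()):
            if pg is not None and pg.buffer(tol).contains(_ShPoint(x)):
                return i
        return -1


# ---------------------------------------------------------------------------
# feasibility of single points


def _base_starts() -> np.ndarray:
    """The documented multi-start set for the 2x2 completion block W.

    Identity, negated identity, and N_RANDOM_STARTS draws from a fixed
    seeded stream.
    """
    rng = np.random.default_rng(_START_SEED)
    starts = [np.array([1.0, 0.0, 0.0, 1.0]), np.array([-1.0, 0.0, 0.0, -1.0])]
    for _ in range(N_RANDOM_STARTS):
        starts.append(rng.normal(scale=1.5, size=4))
    return np.array(starts)


_BASE_STARTS = _base_starts()


class _Feasibility3:
    """Feasibility engine for s = 3 with a cache of successful completions."""

    def __init__(self, svd: TruncatedSVDResult, params: FeasibilityParams):
        if svd.s != 3:
            raise ValueError("three-component engine requires s = 3")
        self.svd = svd
        self.params = params
        self.US = np.ascontiguousarray(svd.US)
        self.V = np.ascontiguousarray(svd.V)
        self.eps = float(params.epsilon)
        self.delta2 = float(params.delta) ** 2
        self.cache: list[np.ndarray] = []
        self._cache_cap = 32

    def spectrum_shortfall(self, x) -> float:
        """Shortfall of the first spectral column alone (W-independent)."""
        prof = self.V[:, 0] + x[0] * self.V[:, 1] + x[1] * self.V[:, 2]
        mx = np.max(np.abs(prof))
        if mx == 0:
            return 0.0
        return max(0.0, -prof.min() / mx - self.eps)

    def _remember(self, W: np.ndarray) -> None:
        for w in self.cache:
            if np.max(np.abs(w - W)) < 1e-6:
                return
        self.cache.append(W.copy())
        if len(self.cache) > self._cache_cap:
            self.cache.pop(0)

    def check(self, x, warm: np.ndarray | None = None) -> FeasibilityCheck:
        x = np.asarray(x, dtype=float)
        s1 = self.spectrum_shortfall(x)
        if s1 * s1 > self.delta2:
            return FeasibilityCheck(False, s1 * s1, None)
        # cheap pass: warm start and cached completions evaluated directly
        direct = ([warm] if warm is not None else []) + self.cache
        best_direct = None
        for w in direct:
            f = violation3(x[0], x[1], w[0], w[1], w[2], w[3], self.US, self.V, self.eps)
            if f <= self.delta2:
                self._remember(w)
                return FeasibilityCheck(True, float(f), np.asarray(w, float))
            if best_direct is None or f < best_direct[0]:
                best_direct = (f, w)
        starts = _BASE_STARTS
        if warm is not None:
            starts = np.vstack([np.asarray(warm, float).reshape(1, 4), starts])
        f, w = min_violation3(
            x[0], x[1], starts, self.US, self.V, self.eps, self.delta2, _NM_MAXITER
        )
        feasible = f <= self.delta2
        if feasible:
            self._remember(w)
        return FeasibilityCheck(bool(feasible), float(f), w)


def _check_two_component(svd, x, params) -> FeasibilityCheck:
    """Multi-start search over the scalar completion for s = 2."""
    from scipy.optimize import minimize_scalar

    delta2 = params.delta**2

    def objective(w):
        return feasibility_violation(svd, build_T([x], [[w]]), params)

    rng = np.random.default_rng(_START_SEED)
    starts = [1.0, -1.0] + list(rng.normal(scale=1.5, size=N_RANDOM_STARTS))
    best = np.inf
    for w0 in starts:
        f0 = objective(w0)
        best = min(best, f0)
        if best <= delta2:
            return FeasibilityCheck(True, best, np.array([w0]))
        res = minimize_scalar(
            objective, bounds=(w0 - 3.0, w0 + 3.0), method="bounded",
            options={"xatol": 1e-8, "maxiter": 80},
        )
        if res.fun < best:
            best = float(res.fun)
            if best <= delta2:
                return FeasibilityCheck(True, best, np.array([res.x]))
    return FeasibilityCheck(False, float(best), None)


def point_feasible(
    svd: TruncatedSVDResult,
    x,
    params: FeasibilityParams | None = None,
    warm: np.ndarray | None = None,
    engine: "_Feasibility3 | None" = None,
) -> FeasibilityCheck:
    """Can the AFS point ``x`` be completed to a nonnegative factorization?

    Minimizes the feasibility violation over the completion block ``W``
    (multi-start local search: identity, negated identity and a fixed
    seeded set of random starts) and accepts when the minimum is at most
    ``delta**2``.  Supported for s = 2 and s = 3.
    """
    params = params or FeasibilityParams()
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if svd.s == 2:
        return _check_two_component(svd, float(x[0]), params)
    if svd.s == 3:
        eng = engine or _Feasibility3(svd, params)
        return eng.check(x, warm=warm)
    raise NotImplementedError("AFS feasibility is implemented for s in {2, 3}")


# ---------------------------------------------------------------------------
# s = 2: closed-form intervals


def afs_two_component(
    svd: TruncatedSVDResult, params: FeasibilityParams | None = None
) -> AFSRegion:
    """Both AFS intervals of a two-component system.

    With spectra parameterized as ``V[:,0] + x*V[:,1]``, entrywise
    nonnegativity bounds ``x`` to an interval whose endpoints are extreme
    ratios ``-V[j,0]/V[j,1]`` (partitioned by the sign of ``V[j,1]``), and
    the nonnegativity of the dual concentration columns excludes the middle
    segment between the extreme ratios ``sigma_2 U[j,1] / (sigma_1 U[j,0])``.
    The closed form holds for ``epsilon = 0``; positive ``epsilon`` weakly
    enlarges both intervals, and the endpoints are then refined by bisection
    on the exact relaxed feasibility test.
    """
    params = params or FeasibilityParams()
    if svd.s != 2:
        raise ValueError("afs_two_component requires s = 2")
    V1, V2 = svd.V[:, 0], svd.V[:, 1]
    U1, U2 = svd.U[:, 0], svd.U[:, 1]
    s1, s2 = svd.Sigma

    pos = V2 > 0
    neg = V2 < 0
    s_lo = np.max(-V1[pos] / V2[pos]) if np.any(pos) else -np.inf
    s_hi = np.min(-V1[neg] / V2[neg]) if np.any(neg) else np.inf

    mask = np.abs(U1) > 1e-12 * np.max(np.abs(U1))
    ratios = s2 * U2[mask] / (s1 * U1[mask])
    r_min, r_max = float(np.min(ratios)), float(np.max(ratios))

    lower = [max(s_lo, -1e6), r_min]
    upper = [r_max, min(s_hi, 1e6)]
    if params.epsilon > 0:
        lower = _refine_interval(svd, lower, params)
        upper = _refine_interval(svd, upper, params)
    polys = [np.array([[lower[0]], [lower[1]]]), np.array([[upper[0]], [upper[1]]])]
    return AFSRegion(
        factor_side=SPECTRAL, polygons=polys, params=params, validate=False
    )


def _refine_interval(svd, interval, params) -> list:
    """Expand closed-form (epsilon = 0) endpoints to the relaxed boundary."""
    lo, hi = interval
    width = max(hi - lo, 1e-6)
    out = []
    for endpoint, direction in ((lo, -1.0), (hi, 1.0)):
        inner = endpoint
        outer = endpoint + direction * 0.5 * width
        steps = 0
        while point_feasible(svd, [outer], params).feasible and steps < 40:
            inner = outer
            outer += direction * 0.5 * width
            steps += 1
        for _ in range(40):
            if abs(outer - inner) <= params.eps_b:
                break
            mid = 0.5 * (inner + outer)
            if point_feasible(svd, [mid], params).feasible:
                inner = mid
            else:
                outer = mid
        out.append(inner)
    return out


# ---------------------------------------------------------------------------
# s = 3: seeding, tracing and the grid oracle


def _row_points(svd: TruncatedSVDResult) -> np.ndarray:
    """Normalized AFS coordinates of the data rows.

    Row ``i`` of ``D`` has expansion coefficients ``Sigma * U[i, :]`` in the
    right singular basis, so its AFS point is available from the SVD alone.
    Rows with a near-zero leading coefficient are dropped (they cannot be
    normalized to leading coefficient 1).
    """
    A = svd.US  # (k, 3): row i coefficients
    lead = A[:, 0]
    norms = np.linalg.norm(A, axis=1)
    ok = np.abs(lead) > 1e-10 * np.maximum(norms, 1e-300)
    pts = A[ok, 1:] / lead[ok, np.newaxis]
    return pts


def _firpol_polygon(svd: TruncatedSVDResult, pad: float = 1.2):
    """The convex region where the first spectrum alone is nonnegative.

    Intersection of the half-planes ``V[j,0] + x1 V[j,1] + x2 V[j,2] >= 0``,
    clipped to a generous box around the data-row points.  This region
    bounds the AFS, so its (padded) bounding box is a safe search window.
    """
    pts = _row_points(svd)
    scale = max(1.0, float(np.max(np.abs(pts))) if pts.size else 1.0)
    world = _sh_box(-40 * scale, -40 * scale, 40 * scale, 40 * scale)
    region = world
    V = svd.V
    vmax = np.max(np.abs(V[:, 0]))
    for j in range(V.shape[0]):
        a0, a1, a2 = V[j]
        nrm = np.hypot(a1, a2)
        if nrm < 1e-14 * max(vmax, 1e-300):
            continue
        # half-plane a0 + a1 x + a2 y >= 0 as a large polygon
        # boundary line point p0 and direction d
        p0 = np.array([-a0 * a1, -a0 * a2]) / (nrm * nrm)
        d = np.array([-a2, a1]) / nrm
        nvec = np.array([a1, a2]) / nrm
        L = 200 * scale
        quad = _ShPolygon(
            [
                p0 + L * d,
                p0 - L * d,
                p0 - L * d + L * nvec,
                p0 + L * d + L * nvec,
            ]
        )
        region = region.intersection(quad)
        if region.is_empty:
            break
    if region.is_empty:
        return None, None
    minx, miny, maxx, maxy = region.bounds
    cx, cy = 0.5 * (minx + maxx), 0.5 * (miny + maxy)
    wx, wy = pad * (maxx - minx), pad * (maxy - miny)
    bbox = (cx - wx / 2, cy - wy / 2, cx + wx / 2, cy + wy / 2)
    return region, bbox


def _certify_batch(points, W_list, US, V, eps, delta2):
    """Vectorized feasibility certification of many points against fixed W.

    For a fixed completion W the violation is a cheap function of the point
    because the dual directions are affine in the homogeneous coordinates
    ``(1, x1, x2)``.  Returns a boolean mask of points certified feasible by
    at least one W.  Points not certified remain undecided.
    """
    points = np.asarray(points, dtype=float)
    N = points.shape[0]
    H = np.column_stack([np.ones(N), points])
    certified = np.zeros(N, dtype=bool)

    # spectral column 1 is W-independent
    S1 = H @ V.T  # (N, n)
    mx = np.max(np.abs(S1), axis=1)
    mx = np.where(mx > 0, mx, 1.0)
    short_s1 = np.maximum(0.0, -S1.min(axis=1) / mx - eps)
    del S1

    def skew(r):
        return np.array(
            [[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0]], dtype=float
        )

    def col_short(A):
        mxa = np.max(np.abs(A), axis=1)
        mxa = np.where(mxa > 0, mxa, 1.0)
        return np.maximum(0.0, -A.min(axis=1) / mxa - eps)

    def vec_short(v):
        m = np.max(np.abs(v))
        if m == 0:
            return 0.0
        return max(0.0, -v.min() / m - eps)

    for w in W_list:
        undecided = ~certified
        if not np.any(undecided):
            break
        r2 = np.array([1.0, w[0], w[1]])
        r3 = np.array([1.0, w[2], w[3]])
        t1 = np.cross(r2, r3)
        dets = H[undecided] @ t1
        scale = max(1.0, np.max(np.abs(points)), np.max(np.abs(w))) ** 3
        ok = np.abs(dets) > 1e-12 * scale
        sgn = np.sign(dets)

        s2v = V @ r2
        s3v = V @ r3
        short_s23 = vec_short(s2v) ** 2 + vec_short(s3v) ** 2

        C1dir = US @ t1
        c1_plus = vec_short(C1dir) ** 2
        c1_minus = vec_short(-C1dir) ** 2
        short_c1 = np.where(sgn >= 0, c1_plus, c1_minus)

        M2 = US @ skew(r3)
        M3 = -US @ skew(r2)
        C2 = (H[undecided] @ M2.T) * sgn[:, np.newaxis]
        C3 = (H[undecided] @ M3.T) * sgn[:, np.newaxis]
        total = (
            short_s1[undecided] ** 2
            + short_s23
            + short_c1
            + col_short(C2) ** 2
            + col_short(C3) ** 2
        )
        newly = ok & (total <= delta2)
        idx = np.flatnonzero(undecided)
        certified[idx[newly]] = True
    return certified


def afs_grid_oracle(
    svd: TruncatedSVDResult,
    bbox,
    resolution: int,
    params: FeasibilityParams | None = None,
    warm_W=None,
    engine: _Feasibility3 | None = None,
) -> np.ndarray:
    """Brute-force feasibility mask on a regular grid (test oracle).

    ``bbox = (xmin, ymin, xmax, ymax)``; the returned mask has shape
    ``(resolution, resolution)`` with ``mask[i, j]`` the feasibility of the
    cell *center* at row i (y axis) and column j (x axis).
    """
    params = params or FeasibilityParams()
    if svd.s != 3:
        raise ValueError("the grid oracle is implemented for s = 3")
    if resolution > 500:
        raise ValueError("resolution capped at 500")
    xmin, ymin, xmax, ymax = bbox
    xs = xmin + (np.arange(resolution) + 0.5) * (xmax - xmin) / resolution
    ys = ymin + (np.arange(resolution) + 0.5) * (ymax - ymin) / resolution
    XX, YY = np.meshgrid(xs, ys)
    pts = np.column_stack([XX.ravel(), YY.ravel()])

    eng = engine or _Feasibility3(svd, params)
    W_list = [np.asarray(w, float).ravel() for w in (warm_W or [])]
    for w in eng.cache:
        W_list.append(w)
    if not W_list:
        W_list = [s.copy() for s in _BASE_STARTS[:2]]

    mask = np.zeros(pts.shape[0], dtype=bool)
    chunk = 8192
    for lo in range(0, pts.shape[0], chunk):
        sl = slice(lo, min(lo + chunk, pts.shape[0]))
        mask[sl] = _certify_batch(
            pts[sl], W_list, eng.US, eng.V, eng.eps, eng.delta2
        )
    # undecided points: full multi-start check (cheap spectral reject inside)
    undecided = np.flatnonzero(~mask)
    for i in undecided:
        mask[i] = eng.check(pts[i]).feasible
    return mask.reshape(resolution, resolution)


# --- boundary tracing -------------------------------------------------------


def _trace_subset(eng: _Feasibility3, seed, seed_W, eps_b, r_max):
    """Trace one AFS subset boundary by adaptive radial bisection.

    From the interior ``seed`` the boundary is located along each ray by
    doubling steps followed by bisection to radial precision ``eps_b``;
    angular directions are refined until the polygon chord midpoints deviate
    from the traced boundary by less than a sagitta tolerance derived from
    the subset extent.  Assumes the subset is star-shaped as seen from the
    seed, which holds for the compact AFS subsets this package targets.
    """
    seed = np.asarray(seed, dtype=float)

    def boundary(theta, warm):
        d = np.array([np.cos(theta), np.sin(theta)])
        r_in, w_in = 0.0, warm
        r_out = None
        r = max(4 * eps_b, 1e-3 * r_max)
        while r <= r_max:
            res = eng.check(seed + r * d, warm=w_in)
            if res.feasible:
                r_in, w_in = r, res.W
                r *= 2.0
            else:
                r_out = r
                break
        if r_out is None:
            raise SeedingError(
                "feasible region appears unbounded along a ray; bad seed or SVD"
            )
        while r_out - r_in > eps_b:
            mid = 0.5 * (r_in + r_out)
            res = eng.check(seed + mid * d, warm=w_in)
            if res.feasible:
                r_in, w_in = mid, res.W
            else:
                r_out = mid
        return seed + r_in * d, w_in

    n0 = 16
    thetas = [2 * np.pi * i / n0 for i in range(n0)] + [2 * np.pi]
    pts = []
    warm = seed_W
    for th in thetas:
        p, warm = boundary(th, warm)
        pts.append(p)

    extent = max(
        np.max([np.linalg.norm(p - q) for p in pts for q in pts]), 4 * eps_b
    )
    sag_tol = max(eps_b, 2.5e-4 * extent)
    max_spacing = extent / 10.0
    min_gap = 2 * np.pi / 4096

    # adaptive refinement of adjacent angle pairs (unwrapped angles)
    accepted = list(zip(thetas[:-1], pts[:-1]))
    work = [
        (thetas[i], pts[i], thetas[i + 1], pts[i + 1]) for i in range(len(thetas) - 1)
    ]
    while work:
        th1, p1, th2, p2 = work.pop()
        if th2 - th1 <= min_gap:
            continue
        thm = 0.5 * (th1 + th2)
        pm, _ = boundary(thm, seed_W)
        accepted.append((thm, pm))
        chord = np.linalg.norm(p2 - p1)
        if chord > 1e-300:
            tvec = (p2 - p1) / chord
            dev = abs(tvec[0] * (pm - p1)[1] - tvec[1] * (pm - p1)[0])
        else:
            dev = np.linalg.norm(pm - p1)
        if dev > sag_tol or chord > max_spacing:
            work.append((th1, p1, thm, pm))
            work.append((thm, pm, th2, p2))
    accepted.sort(key=lambda e: e[0])
    poly = np.array([p for _, p in accepted])
    # drop duplicate consecutive vertices
    keep = np.ones(len(poly), dtype=bool)
    for i in range(1, len(poly)):
        if np.linalg.norm(poly[i] - poly[i - 1]) < 0.25 * eps_b:
            keep[i] = False
    return poly[keep]


def _candidate_seeds(svd: TruncatedSVDResult, eng: _Feasibility3):
    """Feasible seed candidates: data-row points, duality intersections and
    a coarse feasibility grid over the search window.

    Returns (list of (point, W) seeds, firpol bbox).
    """
    from scipy.spatial import ConvexHull

    from .duality import dual_line, intersect_lines, profile_to_afs_point  # cycle-free

    firpol, bbox = _firpol_polygon(svd)
    if firpol is None:
        raise SeedingError("the first-spectrum nonnegativity region is empty")

    seeds: list[tuple[np.ndarray, np.ndarray]] = []

    def consider(pt) -> bool:
        pt = np.asarray(pt, dtype=float)
        if not np.all(np.isfinite(pt)):
            return False
        res = eng.check(pt)
        if res.feasible:
            seeds.append((pt, res.W))
            return True
        return False

    for p in _row_points(svd):
        consider(p)

    # complementary-side extreme profiles (convex hull of column points) give
    # duality candidates for subsets containing no data profile
    tsvd = transpose_svd(svd)
    col_pts = _row_points(tsvd)
    hull_idx = (
        ConvexHull(col_pts).vertices if col_pts.shape[0] > 3 else range(len(col_pts))
    )
    comp_eng = _Feasibility3(tsvd, eng.params)
    comp_feasible = [
        col_pts[i] for i in hull_idx if comp_eng.check(col_pts[i]).feasible
    ]
    for i in range(len(comp_feasible)):
        for j in range(i + 1, min(i + 4, len(comp_feasible))):
            la = dual_line(comp_feasible[i], svd)
            lb = dual_line(comp_feasible[j], svd)
            try:
                pt = intersect_lines(la, lb)
            except ValueError:
                continue
            consider(pt)
    return seeds, bbox, firpol


def afs_three_component(
    svd: TruncatedSVDResult,
    side: str = SPECTRAL,
    params: FeasibilityParams | None = None,
    grid_resolution: int = 40,
    engine_out: list | None = None,
) -> AFSRegion:
    """The AFS of a three-component system, as up to three disjoint polygons.

    ``side`` selects the spectral factor (work on D) or the concentrational
    factor (identical machinery on the transposed matrix).  Subsets are
    found from three candidate sources — the AFS points of the data rows,
    intersections of dual lines of feasible complementary-side profiles,
    and a coarse feasibility grid over the search window — then each is
    traced to boundary precision ``eps_b``.  ``engine_out``, if given, is a
    list that receives the feasibility engine (exposes the completion cache
    for reuse, e.g. by the grid oracle).
    """
    params = params or FeasibilityParams()
    if svd.s != 3:
        raise ValueError("afs_three_component requires s = 3")
    if side == CONCENTRATIONAL:
        work = transpose_svd(svd)
    elif side == SPECTRAL:
        work = svd
    else:
        raise ValueError(f"unknown side {side!r}")

    eng = _Feasibility3(work, params)
    if engine_out is not None:
        engine_out.append(eng)
    seeds, bbox, firpol = _candidate_seeds(work, eng)

    xmin, ymin, xmax, ymax = bbox
    r_max = 4 * np.hypot(xmax - xmin, ymax - ymin)

    polygons: list[np.ndarray] = []
    shapes: list = []

    def already_covered(pt) -> bool:
        p = _ShPoint(pt)
        return any(sh.buffer(4 * params.eps_b).contains(p) for sh in shapes)

    def trace_from(pt, W) -> None:
        poly = _trace_subset(eng, pt, W, params.eps_b, r_max)
        if len(poly) < 3:
            poly = np.vstack(
                [pt + params.eps_b * np.array([np.cos(t), np.sin(t)]) for t in
                 (0.0, 2.0944, 4.1888)]
            )
        sh = _ShPolygon(poly)
        if not sh.is_valid:
            sh = sh.buffer(0)
        polygons.append(poly)
        shapes.append(sh)

    for pt, W in seeds:
        if len(polygons) >= 3:
            break
        if not already_covered(pt):
            trace_from(pt, W)

    if len(polygons) < 3:
        # coarse grid sweep for subsets containing no candidate point
        res = grid_resolution
        xs = xmin + (np.arange(res) + 0.5) * (xmax - xmin) / res
        ys = ymin + (np.arange(res) + 0.5) * (ymax - ymin) / res
        XX, YY = np.meshgrid(xs, ys)
        pts = np.column_stack([XX.ravel(), YY.ravel()])
        inside = np.array([firpol.contains(_ShPoint(p)) for p in pts])
        order = np.flatnonzero(inside)
        for i in order:
            if len(polygons) >= 3:
                break
            pt = pts[i]
            if already_covered(pt):
                continue
            chk = eng.check(pt)
            if chk.feasible:
                trace_from(pt, chk.W)

    if not polygons:
        raise SeedingError("no feasible seed points found")

    labels = [f"component-{i + 1}" for i in range(len(polygons))]
    return AFSRegion(
        factor_side=side,
        polygons=polygons,
        params=params,
        component_labels=labels,
        validate=False,
    )
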