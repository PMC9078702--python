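"""Compiled kernels for the inner feasibility optimization (s = 3).

The AFS boundary tracing and the grid oracle evaluate the relaxed
nonnegativity penalty millions of times for 3x3 transforms.  These kernels
duplicate :func:`mcrafs.factor_core.feasibility_violation` for the s=3 case
with a hand-rolled 3x3 adjugate inverse and a small Nelder-Mead search over
the 2x2 completion block W; equivalence with the reference implementation
is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1e300  # singular-transform sentinel (stands in for +inf)


@njit(cache=True, fastmath=False)
def violation3(x1, x2, w11, w12, w21, w22, US, V, eps):
    """Relaxed-nonnegativity penalty of T = [[1,x1,x2],[1,w11,w12],[1,w21,w22]].

    Returns BIG for (numerically) singular T.
    """
    # determinant by cofactor expansion along the first column of ones
    m1 = w11 * w22 - w12 * w21
    m2 = x1 * w22 - x2 * w21
    m3 = x1 * w12 - x2 * w11
    det = m1 - m2 + m3
    scale = 1.0
    for v in (x1, x2, w11, w12, w21, w22):
        av = abs(v)
        if av > scale:
            scale = av
    if abs(det) <= 1e-12 * scale * scale * scale:
        return BIG

    # inverse via adjugate (columns of inv(T) are the dual directions)
    inv00 = m1 / det
    inv01 = -(x1 * w22 - x2 * w21) / det
    inv02 = (x1 * w12 - x2 * w11) / det
    inv10 = -(w22 - w12) / det
    inv11 = (w22 - x2) / det
    inv12 = -(w12 - x2) / det
    inv20 = (w21 - w11) / det
    inv21 = -(w21 - x1) / det
    inv22 = (w11 - x1) / det

    k = US.shape[0]
    n = V.shape[0]
    total = 0.0

    # concentration columns C[:, i] = US @ inv(T)[:, i]
    for i in range(3):
        if i == 0:
            a, b, c = inv00, inv10, inv20
        elif i == 1:
            a, b, c = inv01, inv11, inv21
        else:
            a, b, c = inv02, inv12, inv22
        mn = 1e300
        mx = 0.0
        for j in range(k):
            v = US[j, 0] * a + US[j, 1] * b + US[j, 2] * c
            if v < mn:
                mn = v
            av = abs(v)
            if av > mx:
                mx = av
        if mx == 0.0:
            mx = 1.0
        short = -mn / mx - eps
        if short > 0.0:
            total += short * short

    # spectral columns S[:, i] = V @ T[i, :]
    for i in range(3):
        if i == 0:
            a, b, c = 1.0, x1, x2
        elif i == 1:
            a, b, c = 1.0, w11, w12
        else:
            a, b, c = 1.0, w21, w22
        mn = 1e300
        mx = 0.0
        for j in range(n):
            v = V[j, 0] * a + V[j, 1] * b + V[j, 2] * c
            if v < mn:
                mn = v
            av = abs(v)
            if av > mx:
                mx = av
        if mx == 0.0:
            mx = 1.0
        short = -mn / mx - eps
        if short > 0.0:
            total += short * short

    return total


@njit(cache=True)
def _nm_minimize(x1, x2, w0, US, V, eps, ftarget, maxiter):
    """Nelder-Mead over the 4 entries of W, with early exit at ftarget."""
    ndim = 4
    npts = 5
    # initial simplex around w0
    simplex = np.empty((npts, ndim))
    fvals = np.empty(npts)
    for i in range(npts):
        for j in range(ndim):
            simplex[i, j] = w0[j]
        if i > 0:
            step = 0.25 * (abs(w0[i - 1]) + 0.5)
            simplex[i, i - 1] += step
    for i in range(npts):
        fvals[i] = violation3(
            x1, x2, simplex[i, 0], simplex[i, 1], simplex[i, 2], simplex[i, 3], US, V, eps
        )
        if fvals[i] <= ftarget:
            return fvals[i], simplex[i].copy()

    alpha, gamma, rho, sig = 1.0, 2.0, 0.5, 0.5
    centroid = np.empty(ndim)
    for _ in range(maxiter):
        order = np.argsort(fvals)
        simplex = simplex[order]
        fvals = fvals[order]
        if fvals[0] <= ftarget:
            return fvals[0], simplex[0].copy()
        # convergence: simplex collapsed in f
        if fvals[npts - 1] < BIG and fvals[npts - 1] - fvals[0] <= 1e-14 * (
            1.0 + abs(fvals[0])
        ):
            break
        for j in range(ndim):
            csum = 0.0
            for i in range(npts - 1):
                csum += simplex[i, j]
            centroid[j] = csum / (npts - 1)
        # reflection
        xr = centroid + alpha * (centroid - simplex[npts - 1])
        fr = violation3(x1, x2, xr[0], xr[1], xr[2], xr[3], US, V, eps)
        if fr < fvals[0]:
            # expansion
            xe = centroid + gamma * (xr - centroid)
            fe = violation3(x1, x2, xe[0], xe[1], xe[2], xe[3], US, V, eps)
            if fe < fr:
                simplex[npts - 1] = xe
                fvals[npts - 1] = fe
            else:
                simplex[npts - 1] = xr
                fvals[npts - 1] = fr
        elif fr < fvals[npts - 2]:
            simplex[npts - 1] = xr
            fvals[npts - 1] = fr
        else:
            # contraction
            if fr < fvals[npts - 1]:
                xc = centroid + rho * (xr - centroid)
            else:
                xc = centroid + rho * (simplex[npts - 1] - centroid)
            fc = violation3(x1, x2, xc[0], xc[1], xc[2], xc[3], US, V, eps)
            if fc < min(fr, fvals[npts - 1]):
                simplex[npts - 1] = xc
                fvals[npts - 1] = fc
            else:
                # shrink
                for i in range(1, npts):
                    simplex[i] = simplex[0] + sig * (simplex[i] - simplex[0])
                    fvals[i] = violation3(
                        x1,
                        x2,
                        simplex[i, 0],
                        simplex[i, 1],
                        simplex[i, 2],
                        simplex[i, 3],
                        US,
                        V,
                        eps,
                    )
                    if fvals[i] <= ftarget:
                        return fvals[i], simplex[i].copy()
    best = np.argmin(fvals)
    return fvals[best], simplex[best].copy()


@njit(cache=True)
def min_violation3(x1, x2, starts, US, V, eps, ftarget, maxiter):
    """Multi-start Nelder-Mead; returns (best value, best W flat).

    ``starts`` is an (m, 4) array of flattened W starting blocks.  Stops at
    the first start reaching ``ftarget`` (feasibility established).
    """
    best_f = BIG
    best_w = starts[0].copy()
    for i in range(starts.shape[0]):
        f0 = violation3(
            x1, x2, starts[i, 0], starts[i, 1], starts[i, 2], starts[i, 3], US, V, eps
        )
        if f0 <= ftarget:
            return f0, starts[i].copy()
        f, w = _nm_minimize(x1, x2, starts[i], US, V, eps, ftarget, maxiter)
        if f < best_f:
            best_f = f
            best_w = w
        if best_f <= ftarget:
            break
    return best_f, best_w
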