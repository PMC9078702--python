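"""Hard-model kinetics of the consecutive protonation/dimerization scheme.

The titration converts the free dye (component 1) via a protonated dimer
(component 2) into the protonated monomer (component 3)::

    2 c1 + H+  -> c2        (rate coefficient k1)
      c2 + H+  -> 2 c3      (rate coefficient k2)

Both steps consume one equivalent of acid, the back reactions are frozen
(superacid titrant), and the stoichiometry implies the closure (mass
balance) ``c1 + 2 c2 + c3 = c0`` along the whole titration.  Because the
data are titration grades rather than a time series, the model is
propagated in the *added-acid* coordinate ``a``: each increment of acid is
split between the two reactions in proportion to their instantaneous rates,

    dc1/da = -2 r1,  dc2/da = r1 - r2,  dc3/da = 2 r2,
    r1 = k1 c1^2 / (k1 c1^2 + k2 c2 + eta),
    r2 = k2 c2   / (k1 c1^2 + k2 c2 + eta),

with a tiny guard ``eta`` keeping the fractions defined once both educts
are exhausted.  Only the *ratio* of the two rate coefficients is
identifiable from such data (the rate fractions are invariant under a
common rescaling of k1, k2); fitted models are therefore reported in the
gauge ``k1 c0^2 + k2 c0 = 1``, and the default model obeys the same gauge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = ["KineticModel", "simulate_titration", "fit_kinetics", "reldiff"]

ETA = 1e-30

#: default total dye concentration, mol/l
DEFAULT_C0 = 9.84269e-4


@dataclass
class KineticModel:
    """Rate coefficients of the two-step titration model.

    ``k1`` (l/mol per unit acid fraction) weights the dimerization rate
    ``k1*c1^2``; ``k2`` (dimensionless per mol/l) the dimer-splitting rate
    ``k2*c2``.  The reverse coefficients are fixed to zero by default
    (irreversible superacid titration).  ``c0`` is the total dye
    concentration entering the closure.
    """

    k1: float
    k2: float
    c0: float = DEFAULT_C0
    k1_rev: float = 0.0
    k2_rev: float = 0.0

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("rate coefficients must be nonnegative")
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if self.k1_rev != 0.0 or self.k2_rev != 0.0:
            raise NotImplementedError("reverse reactions are not modeled")

    def normalized(self) -> "KineticModel":
        """The same model in the gauge ``k1 c0^2 + k2 c0 = 1``."""
        scale = self.k1 * self.c0**2 + self.k2 * self.c0
        if scale <= 0:
            raise ValueError("cannot normalize an all-zero rate model")
        return KineticModel(k1=self.k1 / scale, k2=self.k2 / scale, c0=self.c0)


def default_model(c0: float = DEFAULT_C0) -> KineticModel:
    """Gauge-normalized default rates: dimerization initially dominant.

    ``k1 c0^2 = 0.9`` and ``k2 c0 = 0.1`` let the dimer accumulate to a
    substantial mid-titration population before it is split, giving three
    well-expressed components.
    """
    return KineticModel(k1=0.9 / c0**2, k2=0.1 / c0, c0=c0)


def simulate_titration(model: KineticModel, acid_grid: np.ndarray) -> np.ndarray:
    """Concentrations ``(k, 3)`` of the three components at the acid grid.

    ``acid_grid`` must be nondecreasing and start at 0 (mol/l of added
    acid); the initial state is ``(c0, 0, 0)``.  Closure ``c1+2c2+c3 = c0``
    is conserved by construction of the ODE and checked to 1e-9 relative.
    """
    acid_grid = np.asarray(acid_grid, dtype=float)
    if acid_grid.ndim != 1 or acid_grid.size < 1:
        raise ValueError("acid_grid must be a 1-D vector")
    if acid_grid[0] != 0.0:
        raise ValueError("acid_grid must start at 0")
    if np.any(np.diff(acid_grid) < 0):
        raise ValueError("acid_grid must be nondecreasing")

    k1, k2, c0 = model.k1, model.k2, model.c0
    a = acid_grid

    if k1 == 0.0:
        # nothing can react: the dimer (and hence the product) never forms
        return np.tile((c0, 0.0, 0.0), (a.size, 1))
    if k2 == 0.0:
        # single-step consumption 2 c1 + H+ -> c2 until c1 is exhausted
        c1 = np.maximum(c0 - 2.0 * a, 0.0)
        c2 = 0.5 * (c0 - c1)
        return np.column_stack([c1, c2, np.zeros_like(c1)])

    # While acid is consumed, the educt mass obeys c1 + c2 = c0 - a exactly
    # (every acid equivalent removes one educt unit), so the state reduces
    # to the fraction rho = c1/(c1 + c2).  In the log-remaining-mass
    # coordinate s = -ln(1 - a/c0) the reduced ODE
    #     drho/ds = rho - 2 r1,   r1 = k1 rho^2 m / (k1 rho^2 m + k2 (1-rho))
    # has a bounded, corner-free right-hand side all the way to depletion.
    live = a < c0 * (1.0 - 1e-9)
    C = np.tile((0.0, 0.0, c0), (a.size, 1))
    if np.any(live):
        s_pts = -np.log1p(-a[live] / c0)

        def rhs(s, y):
            rho = min(max(y[0], 0.0), 1.0)
            mrem = c0 * np.exp(-s)
            q1 = k1 * rho * rho * mrem
            q2 = k2 * (1.0 - rho)
            r1 = q1 / (q1 + q2 + ETA)
            return (rho - 2.0 * r1,)

        sol = solve_ivp(
            rhs,
            (0.0, float(s_pts[-1]) if s_pts[-1] > 0 else 1e-12),
            (1.0,),
            t_eval=s_pts,
            method="Radau",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:  # pragma: no cover - integrator diagnostics
            raise RuntimeError(f"titration integration failed: {sol.message}")
        rho = np.clip(sol.y[0], 0.0, 1.0)
        mrem = c0 - a[live]
        C[live, 0] = rho * mrem
        C[live, 1] = (1.0 - rho) * mrem
        C[live, 2] = c0 - mrem * (2.0 - rho)

    # closure c1 + 2 c2 + c3 = c0 holds by construction of the reduction
    closure_err = np.max(np.abs(C @ np.array([1.0, 2.0, 1.0]) - c0)) / c0
    if closure_err > 1e-9:  # pragma: no cover - defensive
        raise RuntimeError(f"closure drift {closure_err:.2e} exceeds 1e-9")
    return C


@njit(cache=True)
def _rho_rhs(rho, a, k1, k2, c0):
    m = c0 - a
    c1 = rho * m
    q1 = k1 * c1 * c1
    q2 = k2 * (1.0 - rho) * m
    r1 = q1 / (q1 + q2 + 1e-300)
    return (rho - 2.0 * r1) / m


@njit(cache=True)
def _rho_trajectory(k1, k2, c0, a_pts):
    """Fixed-step RK4 for the reduced titration ODE (fit inner loop).

    While acid is consumed, ``c1 + c2 = c0 - a`` holds identically, so the
    state reduces to the fraction ``rho = c1/(c1+c2)`` with
    ``drho/da = (rho - 2 r1)/(c0 - a)``.  Steps are capped by a fraction of
    the remaining mass, which keeps explicit RK4 stable as the depletion
    point is approached.
    """
    out = np.empty(a_pts.size)
    rho = 1.0
    a = 0.0
    base = c0 / 600.0
    for i in range(a_pts.size):
        target = a_pts[i]
        while a < target:
            m = c0 - a
            h = min(base, 0.1 * m)
            if a + h > target:
                h = target - a
            k1s = _rho_rhs(rho, a, k1, k2, c0)
            k2s = _rho_rhs(rho + 0.5 * h * k1s, a + 0.5 * h, k1, k2, c0)
            k3s = _rho_rhs(rho + 0.5 * h * k2s, a + 0.5 * h, k1, k2, c0)
            k4s = _rho_rhs(rho + h * k3s, a + h, k1, k2, c0)
            rho += h * (k1s + 2.0 * k2s + 2.0 * k3s + k4s) / 6.0
            if rho < 0.0:
                rho = 0.0
            elif rho > 1.0:
                rho = 1.0
            a += h
        out[i] = rho
    return out


def _simulate_fast(k1, k2, c0, acid_grid):
    """Reduced-model trajectory used inside the fit loop (see above)."""
    grid = np.asarray(acid_grid, dtype=float)
    C = np.empty((grid.size, 3))
    live = grid < c0 * (1.0 - 1e-9)
    rho = _rho_trajectory(k1, k2, c0, grid[live])
    m = c0 - grid[live]
    C[live, 0] = rho * m
    C[live, 1] = (1.0 - rho) * m
    C[live, 2] = c0 - m * (2.0 - rho)
    C[~live] = (0.0, 0.0, c0)
    return C


def fit_kinetics(
    C_target: np.ndarray,
    acid_grid: np.ndarray,
    c0: float,
    seed: int = 0,
    n_grid: int = 4,
):
    """Least-squares fit of the rate coefficients to concentration profiles.

    Runs trust-region least squares in ``(log k1, log k2)`` from a seeded
    ``n_grid x n_grid`` logarithmic grid of starting points and returns the
    best ``(model, fitted trajectory, sse)``.  The returned model is
    gauge-normalized (see module docstring); callers comparing coefficients
    should normalize the reference the same way.
    """
    C_target = np.asarray(C_target, dtype=float)
    acid_grid = np.asarray(acid_grid, dtype=float)
    if C_target.shape != (acid_grid.size, 3):
        raise ValueError("C_target must be (k, 3) matching the acid grid")
    if acid_grid.size < 4:
        raise ValueError("need at least 4 titration points to fit two rates")
    scale = np.linalg.norm(C_target)
    if scale == 0 or np.max(C_target.std(axis=0)) < 1e-12 * c0:
        raise ValueError("flat concentration profiles cannot constrain the rates")

    def residual(logk):
        C = _simulate_fast(np.exp(logk[0]), np.exp(logk[1]), c0, acid_grid)
        return ((C - C_target) / c0).ravel()

    rng = np.random.default_rng(seed)
    # gauge-aware start grid: k1 c0^2 in [1e-2, 1e2], k2 c0 in [1e-2, 1e2]
    g1 = np.log(np.logspace(-2, 2, n_grid) / c0**2)
    g2 = np.log(np.logspace(-2, 2, n_grid) / c0)
    jitter = rng.uniform(-0.1, 0.1, size=(n_grid, n_grid, 2))
    # a cost at machine-noise level cannot be improved by further starts
    cost_floor = max(1e-16 * C_target.size, 1e-3 * np.finfo(float).eps * scale / c0)
    best = None
    for i in range(n_grid):
        for j in range(n_grid):
            x0 = np.array([g1[i] + jitter[i, j, 0], g2[j] + jitter[i, j, 1]])
            lo = np.array([g1[0] - 6.0, g2[0] - 6.0])
            hi = np.array([g1[-1] + 6.0, g2[-1] + 6.0])
            try:
                res = least_squares(residual, x0, method="trf", xtol=1e-12,
                                    ftol=1e-12, gtol=1e-12, max_nfev=120,
                                    bounds=(lo, hi))
            except Exception:  # pragma: no cover - optimizer hiccup
                continue
            if best is None or res.cost < best.cost:
                best = res
            if best.cost < cost_floor:
                break
        if best is not None and best.cost < cost_floor:
            break
    if best is None:
        raise RuntimeError("all kinetic fit starts failed")
    model = KineticModel(
        k1=float(np.exp(best.x[0])), k2=float(np.exp(best.x[1])), c0=c0
    ).normalized()
    C_fit = simulate_titration(model, acid_grid)
    sse = float(np.sum((C_fit - C_target) ** 2))
    return model, C_fit, sse


def reldiff(C_kin: np.ndarray, C_sol: np.ndarray, norm: str = "max") -> np.ndarray:
    """Per-component relative differences between two concentration factors.

    ``norm`` is ``"max"`` (maximum absolute deviation) or ``"euclidean"``;
    each component's difference is normalized by the same norm of the
    reference column ``C_sol[:, i]``.
    """
    C_kin = np.asarray(C_kin, dtype=float)
    C_sol = np.asarray(C_sol, dtype=float)
    if C_kin.shape != C_sol.shape:
        raise ValueError("shape mismatch between compared factors")
    if norm == "max":
        num = np.max(np.abs(C_kin - C_sol), axis=0)
        den = np.max(np.abs(C_sol), axis=0)
    elif norm == "euclidean":
        num = np.linalg.norm(C_kin - C_sol, axis=0)
        den = np.linalg.norm(C_sol, axis=0)
    else:
        raise ValueError("norm must be 'max' or 'euclidean'")
    if np.any(den == 0):
        raise ZeroDivisionError("reference column with zero norm")
    return num / den
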