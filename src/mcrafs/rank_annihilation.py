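"""Middle-component extraction by two rank-1 downdates.

When the first and last rows of a three-component titration matrix are pure
(concentration rows ``(c0, 0, 0)`` and ``(0, 0, c0)``), subtracting the
contributions of the two endpoint components leaves a rank-1 residual whose
leading singular pair is the concentration profile and spectrum of the
middle component (the dimer).

The downdate profiles are built in three steps:

1. ordinary least squares of the data rows onto the two endpoint spectra
   (coefficients ``alpha``, ``beta``);
2. the closure (mass balance) turns the per-row regression deficit into the
   *direction* of the middle concentration profile,
   ``v = (c0 - w1*alpha - w3*beta) / w2``, exactly proportional to the true
   profile for noiseless rank-3 data;
3. plain OLS coefficients absorb part of the middle spectrum into the
   endpoint profiles (the residual spectrum would be obliquely projected),
   so the downdate profiles are refined as ``alpha - mu*v`` and
   ``beta - nu*v`` with ``(mu, nu)`` chosen by a small linear program:
   subtract as much endpoint contribution as possible while keeping the
   residual matrix nonnegative up to a noise-scaled tolerance.  Wherever
   the middle component has spectral windows in which it does not absorb
   but an endpoint does, this pins the downdate at the true profiles.

The residual's rank-1 quality ``sigma_2/sigma_1`` and the most negative
entry of the unit-scaled recovered spectrum are reported as diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .dataio import SpectralDataset

__all__ = [
    "rank1_downdate",
    "middle_component_by_annihilation",
    "RankAnnihilationResult",
    "DegenerateResidualError",
]


class DegenerateResidualError(RuntimeError):
    """The downdated matrix has no significant leading singular value."""


@dataclass
class RankAnnihilationResult:
    """Recovered middle component and diagnostics."""

    conc_profile: np.ndarray  #: (k,) concentration profile, closure-scaled (mol/l)
    spectrum: np.ndarray  #: (n,) spectrum scaled so conc x spectrum ~ residual
    quality: float  #: sigma_2 / sigma_1 of the downdated matrix
    min_negative_rel: float  #: most negative entry of the unit-max spectrum
    mu: float  #: downdate refinement coefficient for the first component
    nu: float  #: downdate refinement coefficient for the last component

    def __iter__(self):
        return iter((self.conc_profile, self.spectrum, self.quality))


def rank1_downdate(D: np.ndarray, conc_profile: np.ndarray, spectrum: np.ndarray):
    """``D - conc_profile @ spectrum.T`` with dimension checks."""
    D = np.asarray(D, dtype=float)
    c = np.asarray(conc_profile, dtype=float).ravel()
    s = np.asarray(spectrum, dtype=float).ravel()
    if D.shape != (c.size, s.size):
        raise ValueError(
            f"downdate dimensions {c.size}x{s.size} do not match D {D.shape}"
        )
    return D - np.outer(c, s)


def middle_component_by_annihilation(
    dataset: SpectralDataset | np.ndarray,
    first_spectrum: np.ndarray,
    last_spectrum: np.ndarray,
    c0: float,
    closure_weights=(1.0, 2.0, 1.0),
) -> RankAnnihilationResult:
    """Recover the middle component after annihilating the endpoint ones.

    ``first_spectrum`` / ``last_spectrum`` are the pure spectra of the
    initial and final species, typically the first and last measured
    spectrum of the titration; ``c0`` is the closure constant.
    """
    D = dataset.absorbance if isinstance(dataset, SpectralDataset) else np.asarray(dataset, float)
    s1 = np.asarray(first_spectrum, dtype=float).ravel()
    s3 = np.asarray(last_spectrum, dtype=float).ravel()
    k, n = D.shape
    if s1.size != n or s3.size != n:
        raise ValueError("endpoint spectra must match the channel count of D")
    w1, w2, w3 = closure_weights

    # row-space consistency warning
    sv_full = np.linalg.svd(D, compute_uv=False)
    U, sv, Vt = np.linalg.svd(D, full_matrices=False)
    r = min(3, min(k, n))
    P = Vt[:r].T @ Vt[:r]
    for name, s_vec in (("first", s1), ("last", s3)):
        res = np.linalg.norm(s_vec - P @ s_vec)
        if res > 0.1 * np.linalg.norm(s_vec):
            warnings.warn(
                f"{name} spectrum has {res / np.linalg.norm(s_vec):.1%} of its "
                "norm outside the dominant row space of D",
                stacklevel=2,
            )

    X = np.column_stack([s1, s3])  # (n, 2)
    coef, *_ = np.linalg.lstsq(X, D.T, rcond=None)
    alpha, beta = coef[0], coef[1]
    v = (c0 - w1 * alpha - w3 * beta) / w2

    mu, nu = _refine_downdate(D, s1, s3, alpha, beta, v, sv_full)
    u1 = alpha - mu * v
    u3 = beta - nu * v
    residual = D - np.outer(u1, s1) - np.outer(u3, s3)

    Ur, svr, Vtr = np.linalg.svd(residual, full_matrices=False)
    if svr[0] <= 1e-12 * max(sv_full[0], 1e-300):
        raise DegenerateResidualError(
            "downdated matrix is numerically zero: no middle component present"
        )
    quality = float(svr[1] / svr[0]) if svr.size > 1 else 0.0
    spec_unit = Vtr[0]
    u_vec = Ur[:, 0]
    imax = np.argmax(np.abs(spec_unit))
    if spec_unit[imax] < 0:
        spec_unit = -spec_unit
        u_vec = -u_vec

    # closure gives the absolute concentration scale of the middle component
    c2_est = (c0 - w1 * u1 - w3 * u3) / w2
    gamma = float(u_vec @ c2_est)
    if gamma <= 0:
        warnings.warn("closure scaling produced a nonpositive scale", stacklevel=2)
        gamma = float(svr[0])
    conc = gamma * u_vec
    spectrum = (svr[0] / gamma) * spec_unit
    min_neg = float(spec_unit.min() / spec_unit.max())
    min_neg = min(min_neg, 0.0)
    return RankAnnihilationResult(
        conc_profile=conc,
        spectrum=spectrum,
        quality=quality,
        min_negative_rel=min_neg,
        mu=float(mu),
        nu=float(nu),
    )


def _refine_downdate(D, s1, s3, alpha, beta, v, sv_full):
    """Choose (mu, nu) maximizing the downdate subject to residual >= -tau.

    The residual ``R0 + mu * v s1^T + nu * v s3^T`` is affine in (mu, nu);
    per-channel minimum ratios reduce the entrywise constraints to one
    constraint per channel.  Falls back to the plain OLS downdate
    (mu = nu = 0) when the program is unbounded or infeasible.
    """
    k, n = D.shape
    # noise-scaled nonnegativity tolerance from the 4th singular value
    floor = sv_full[3] if sv_full.size > 3 else 0.0
    tau = 3.0 * floor / (np.sqrt(k) + np.sqrt(n)) + 1e-12 * sv_full[0]

    R0 = D - np.outer(alpha, s1) - np.outer(beta, s3)
    vmax = np.max(np.abs(v))
    # only rows carrying a meaningful middle-component fraction constrain
    # the program: near-depleted rows have v at the noise level and would
    # contribute arbitrarily amplified spurious bounds
    rows = v > 1e-2 * max(vmax, 1e-300)
    if not np.any(rows):
        return 0.0, 0.0
    ratios = (R0[rows] + tau) / v[rows, np.newaxis]  # (m, n)
    b = ratios.min(axis=0)  # per-channel bound: -mu*s1 - nu*s3 <= b
    A_ub = np.column_stack([-s1, -s3])
    # plain OLS over-subtracts (it absorbs part of the middle component into
    # the endpoint profiles); minimizing (mu, nu) against the residual
    # nonnegativity bounds subtracts as much endpoint contribution as the
    # nonnegativity of the middle component's spectrum allows
    mass = np.array([v[rows].sum() * s1.sum(), v[rows].sum() * s3.sum()])
    res = linprog(
        c=mass,
        A_ub=A_ub,
        b_ub=b,
        bounds=[(None, None), (None, None)],
        method="highs",
    )
    if not res.success:
        warnings.warn(
            "downdate refinement program failed; using plain regression profiles",
            stacklevel=3,
        )
        return 0.0, 0.0
    return float(res.x[0]), float(res.x[1])
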