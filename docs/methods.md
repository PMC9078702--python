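# Methods

This note documents the models, algorithms and numerical choices behind
`mcrafs`. It is written for users who want to understand what the package
computes and where its answers can and cannot be trusted.

## The factor model

A series of `k` mixture spectra over `n` channels forms a matrix
`D ∈ R^{k×n}`. By the Lambert–Beer law, `s` absorbing species with
concentration profiles `C ∈ R^{k×s}` and pure spectra `S ∈ R^{n×s}` give

    D = C Sᵀ,        C ≥ 0,  S ≥ 0.

With the truncated SVD `D ≈ U Σ Vᵀ` (rank `s`), every rank-`s`
factorization can be written

    C = U Σ T⁻¹,     S = V Tᵀ,

for a regular `T ∈ R^{s×s}`. Because each spectrum is determined only up
to scale, the first column of `T` is normalized to the all-ones vector;
the remaining `(s−1)s` entries parameterize the *rotational ambiguity*:
the continuum of nonnegative factorizations consistent with `D`.

Right singular vectors are oriented so their largest-magnitude entry is
positive; the left vectors carry the compensating sign. This makes all
AFS coordinates reproducible across BLAS/LAPACK builds.

## Relaxed nonnegativity

Measured (preprocessed) data and rank truncation both produce small
negative entries, so strict nonnegativity is relaxed: a profile `v`
(a column of `C` or `S`) is accepted when

    min(v) ≥ −ε · max|v|,

i.e. `ε` bounds the relative magnitude of negative entries. The default
`ε = 2×10⁻⁴` is the standard choice for high-SNR UV/Vis data. The
violation of a transform `T` is the sum of squared shortfalls
`max(0, −min(v)/max|v| − ε)²` over all `2s` profiles; a singular `T`
scores `+∞` so optimizers can penalize it smoothly. The normalization by
each profile's own max-abs entry makes the measure invariant under the
intrinsic column rescaling of the factorization; normalizing by a
factor-wide maximum instead would couple the components and is *not* what
is implemented.

## The area of feasible solutions (AFS)

A point `x ∈ R^{s−1}` represents the candidate spectrum
`V[:,0] + x₁V[:,1] + …` (coefficients normalized to leading coefficient
1). `x` belongs to the spectral AFS if some completion `W` of
`T = [[1, x], [1, W]]` drives the violation to (numerically) zero; the
acceptance threshold is `δ²` with `δ = 10⁻⁴`, tying the inner-search
tolerance to the feasibility decision. The concentrational AFS is the
identical construction on `Dᵀ`; the transposed SVD reuses the same
singular vectors (roles of `U` and `V` swapped) so the sign conventions
of the two sides stay mutually consistent. AFS plot coordinates omit `Σ`
on both sides: points are expansion coefficients in the singular-vector
basis itself.

**Inner search (s = 3).** The violation is minimized over the four
entries of `W` by Nelder–Mead from a fixed start set: `W = I`, `W = −I`,
and eight draws from a seeded stream (fixed seed, identical for every
point, so results are deterministic). A point additionally caches every
successful `W` it encounters; cached completions are tried first, which
short-circuits almost all feasible queries. The first spectral column
depends only on `x`, giving a cheap necessary condition that rejects most
infeasible points without any optimization. The hot kernel (3×3 adjugate
inverse plus column shortfalls) and the Nelder–Mead loop are compiled
with numba; the compiled kernel is asserted equal to the plain-numpy
reference implementation in the test suite.

**s = 2 closed form.** With `V₁ ≥ 0` (Perron orientation), spectral
nonnegativity bounds `x` to `[max_{V₂ⱼ>0}(−V₁ⱼ/V₂ⱼ), min_{V₂ⱼ<0}(−V₁ⱼ/V₂ⱼ)]`
and the dual concentration columns exclude the middle segment between
`min` and `max` of `σ₂U₂ⱼ/(σ₁U₁ⱼ)` — the classic two-component
self-modeling bounds. For `ε > 0` the endpoints are refined by bisection
on the exact relaxed test.

**Boundary tracing (s = 3).** Each subset is traced from an interior
seed by radial bisection to precision `ε_b = 10⁻⁴` (coordinate units),
over angular directions refined adaptively until the midpoint of every
boundary chord deviates from the traced boundary by less than a sagitta
tolerance `max(ε_b, 2.5×10⁻⁴ × subset extent)` and chords are shorter
than a tenth of the extent. This bounds the area error of the polygon by
roughly `perimeter × sagitta`, which is what the grid-oracle comparison
in the tests measures. The tracer assumes the subset is star-shaped as
seen from the seed — true for the compact, well-separated subsets this
package targets, and cross-checked against the brute-force oracle; deeply
nonconvex AFS shapes would require a finer angular refinement.

**Seeding.** Feasible seeds come from three sources, in order: AFS
points of the data rows themselves (the expansion coefficients of row `i`
are `Σ U[i,:]`, so no projection is needed; near-pure rows land inside
the low-ambiguity subsets), intersections of dual lines of feasible
profiles from the complementary side (this finds subsets that contain no
measured profile, e.g. an intermediate never observed pure), and a
coarse feasibility grid over the bounding box of the region where the
first spectrum alone is nonnegative (a convex polygon computed by
half-plane clipping). Rows whose leading expansion coefficient is below
`10⁻¹⁰` of the profile norm cannot be normalized and are skipped.

**Grid oracle.** `afs_grid_oracle` evaluates point feasibility at every
cell center of a regular grid. For speed it first certifies points in
bulk against the cached completions (for fixed `W` the dual directions
are affine in the homogeneous point coordinates, so whole batches are
tested with a few matrix products), then falls back to the full
multi-start search for undecided points. It exists as an independent
cross-check of the polygon tracer and is used only in tests and the
acceptance script.

## Duality

From `T⁻¹T = I`: if the first row of `T` is `(1, x)`, every
complementary column `t̃` of `T⁻¹` satisfies `(1, x)·t̃ = 0`. Writing the
concentration point as the normalized `U`-basis coefficients
`y = (σ₂t̃₂/(σ₁t̃₁), σ₃t̃₃/(σ₁t̃₁))` turns this into the dual line

    1 + (σ₁/σ₂) x₁ y₁ + (σ₁/σ₃) x₂ y₂ = 0

in the concentrational AFS plane, and symmetrically in the other
direction (the incidence form is bilinear and symmetric). The σ-ratios
appear because the plot coordinates omit `Σ`; in Σ-included coordinates
the line would read `1 + x·y = 0`. The formula is *verified* in the test
suite against explicit `T⁻¹` algebra for seeded random transforms rather
than assumed.

`complete_factorization` assembles a full `T` from fixed profiles:
three fixes on one side give `T` directly; two fixed spectra plus two
fixed concentration profiles of the same two components pin the third
point on each side via dual-line intersections (the standard titration
workflow: endpoint spectra plus two externally measured concentration
profiles). The result is unique up to positive column scaling (spectra
are returned with unit maximum) and component order (fixed inputs first,
duality-derived component last). Fixes whose combined violation exceeds
`100 δ²` raise an inconsistency error carrying the violation value.

## Bands and closure

`band_envelopes` samples an AFS subset (all boundary vertices plus
seeded rejection-sampled interior points — boundary vertices are always
included so envelope extremes are not sampling-limited) and returns the
pointwise min/max of the reconstructed profiles, each normalized to unit
maximum. The band width is a profile-space picture of the remaining
ambiguity.

The closure (mass-balance) constraint `Σᵢ wᵢ cᵢ(a) = c₀` — here
`c₁ + 2c₂ + c₃ = c₀` with the dimer counting twice — fixes the absolute
concentration scale. `closure_scale` solves the linear least-squares
problem for positive per-column scales over all titration points,
falling back to nonnegative least squares when the unconstrained
solution has nonpositive entries. When the design matrix has condition
number above 10⁶ the scale of some component is not actually determined
by the closure; the result is then flagged ambiguous instead of being
reported silently.

## Rank annihilation

With pure first/last rows (`C(1,:) = (c₀,0,0)`, `C(k,:) = (0,0,c₀)`),
subtracting the two endpoint components' contributions leaves a rank-1
residual whose leading singular pair is the middle component. The
downdate profiles are constructed as follows:

1. OLS of the data rows onto the two endpoint spectra gives coefficients
   `α, β` per row.
2. The closure converts the regression deficit into the exact *direction*
   of the middle profile: `v = (c₀ − w₁α − w₃β)/w₂ ∝ c₂` for rank-3 data.
3. Plain OLS over-subtracts: it absorbs part of the middle spectrum into
   the endpoint profiles, so the residual spectrum would be an oblique
   projection with negative lobes. The downdate profiles `α − μv`,
   `β − νv` are therefore refined by a two-variable linear program that
   subtracts as much endpoint contribution as possible subject to the
   residual staying nonnegative up to a noise-scaled tolerance
   (`3 σ₄/(√k+√n)`, the entrywise noise level estimated from the fourth
   singular value). Wherever an endpoint species absorbs in a window
   where the middle species does not, this pins the downdate at the true
   profiles; without such windows the middle spectrum is determined only
   up to multiples of the endpoint spectra, which is a structural limit
   of rank annihilation, not of this implementation. If the program is
   unbounded or infeasible the plain OLS downdate is used and a warning
   is issued.

The per-channel minimum of the constraint ratios reduces the `k×n`
entrywise constraints to `n`, so the program is tiny. Reported
diagnostics: `σ₂/σ₁` of the residual (rank-1 quality) and the most
negative entry of the unit-maximum recovered spectrum.

## Kinetic hard model

The titration chemistry is a consecutive scheme — protonation-assisted
dimerization of the free dye followed by acid splitting of the dimer —
with closure weights `(1, 2, 1)` and no back reactions (superacid
titrant). Because the data are titration grades, not a time series, the
model is propagated in the added-acid coordinate `a`: each acid increment
splits between the two reactions in proportion to their instantaneous
rates `k₁c₁²` and `k₂c₂`:

    dc₁/da = −2r₁,  dc₂/da = r₁ − r₂,  dc₃/da = 2r₂,
    r₁ = k₁c₁²/(k₁c₁² + k₂c₂ + η),  r₂ = k₂c₂/(k₁c₁² + k₂c₂ + η),

with guard `η = 10⁻³⁰`. This conserves the closure identically and
implies `c₁ + c₂ = c₀ − a` while educts remain: the state reduces to the
educt fraction `ρ = c₁/(c₁+c₂)`, and in the coordinate
`s = −ln(1 − a/c₀)` the reduced ODE `dρ/ds = ρ − 2r₁` is bounded and
corner-free all the way to depletion at `a = c₀`. The accurate path
integrates this reduced form with Radau (`rtol 10⁻¹⁰`); points past
`a = c₀(1 − 10⁻⁹)` are the exact converted state `(0, 0, c₀)`. The
degenerate cases `k₁ = 0` (no reaction) and `k₂ = 0` (single-step
consumption, frozen at `(0, c₀/2, 0)`) have closed forms. The fit's
inner loop uses a compiled fixed-step RK4 on the same reduced ODE
(600 base steps, step capped at a tenth of the remaining educt mass),
accurate to ~2×10⁻⁵·c₀ against Radau.

**Identifiability and gauge.** The rate fractions depend only on the
ratio `k₂/k₁` (up to the unobservable `η`), so `(k₁, k₂)` are defined
only up to a common scale. The package fixes the gauge

    k₁c₀² + k₂c₀ = 1 :

`fit_kinetics` optimizes `(log k₁, log k₂)` from a seeded 4×4
logarithmic start grid (trust-region least squares, bounded), then
normalizes the best fit into the gauge; the default generator rates
(`k₁c₀² = 0.9`, `k₂c₀ = 0.1`, chosen so the dimer accumulates to about a
third of `c₀` mid-titration) satisfy the same gauge, so fitted and true
coefficients are directly comparable. Comparing raw, un-gauged rate
pairs is meaningless for this model class.

`reldiff` reports per-component relative differences between two
concentration factors in the maximum or Euclidean norm, normalized by
the reference column.

## Synthetic data generator

The generator emulates a 12-spectra UV/Vis acid–base titration: 401
channels on 200–600 nm, added acid on `[0, 1.264×10⁻³]` mol/l, total dye
`c₀ = 9.84269×10⁻⁴` mol/l, concentrations from the kinetic model above
(closure holds to machine precision), and Gaussian-band pure spectra
(three bands each, heights ~10³ l/mol giving peak absorbances of order
one). The band layout is chosen so the two endpoint species each have an
exclusive spectral window while the dimer's bands lie strictly inside
the others' support — the hard regime in which the intermediate carries
the dominant rotational ambiguity, mirroring the motivating experiment
where the dimer's spectral subset and the product's concentrational
subset are the large ones.

Noise is additive Gaussian on the absorbance, with standard deviation
`noise_sigma × max(CSᵀ)` from a seeded generator (fixed seed ⇒
bit-identical data). The default `noise_sigma = 2×10⁻⁵` is deliberately
tied to the feasibility tolerance: the rank-3 reconstruction of noisy
data carries relative negative dips of roughly `(σ₁/σ₃) × noise`, and an
AFS analysis at `ε = 2×10⁻⁴` is only meaningful when those dips stay
below `ε`. At `noise_sigma = 10⁻³` (used deliberately in the
rank-estimation and rank-annihilation robustness tests) the dips reach
~6×10⁻³ and the AFS at the default `ε` is empty — the correct, if
unhelpful, answer. What passing tests on this generator do *not* show:
robustness to baseline drift, stray light, wavelength miscalibration or
heteroscedastic noise, none of which are modeled.

The ε-monotonicity checks run on three noiseless instances with
seed-jittered band parameters (centers ±8 nm, widths ±10%, heights
±15%) rather than three noise draws, because at `ε = 0` a noisy instance
has a (near-)empty AFS and the containment statement would be vacuous.

## Problem sizes and runtime

Unit tests use a 12×101-channel synthetic; the acceptance tests and
`scripts/acceptance.py` use the full 12×401 default, a 200×200 oracle
grid over the spectral AFS (the two low-ambiguity subsets are smaller
than one grid cell at that resolution; the zoomed oracle comparisons in
the unit tests resolve them individually), and 12×201 channels for the
three ε-monotonicity instances. The full suite runs in a few minutes on
one CPU; the dominant costs are proving grid points *infeasible* (every
such point pays the full multi-start search) and the six AFS traces of
the monotonicity check.

## Known limitations

- AFS computation is implemented for `s ∈ {2, 3}`; four-component
  systems (point–plane duality) are out of scope.
- The boundary tracer requires subsets that are star-shaped from the
  seed and separated by more than `ε_b`; merging subsets (large `ε`)
  would be traced as one.
- `point_feasible` decides feasibility by local multi-start search; a
  false *infeasible* answer is possible in principle if all ten starts
  miss the feasible completion basin. The completion cache, the
  cross-checks against the grid oracle and the ground-truth membership
  tests bound this risk empirically, but it is not a certificate.
- Rank annihilation recovers the middle spectrum exactly only when the
  endpoint species have spectral windows free of the middle species
  (see above); otherwise an explicit indeterminacy remains.
- The kinetic model is irreversible by construction; fitting reversible
  titrations or extracting equilibrium constants is not supported.
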