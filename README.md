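# mcrafs

**Multivariate curve resolution with areas of feasible solutions.**

`mcrafs` recovers pure-component spectra and concentration profiles from
series of mixture spectra (UV/Vis titrations, reaction monitoring, and by
extension any bilinear spectral data, e.g. proteomics or metabolomics
deconvolution problems). Instead of returning one of the infinitely many
nonnegative factorizations consistent with the data, it computes the *set*
of all of them, shows how external knowledge shrinks that set to a unique
answer, and validates the answer against two independent methods.

## The problem and the model

A series of `k` spectra over `n` channels forms `D ∈ R^{k×n}`; by the
Lambert–Beer law, `s` absorbing species give

    D = C Sᵀ,   C ∈ R^{k×s} ≥ 0 (concentrations),  S ∈ R^{n×s} ≥ 0 (spectra).

Over the truncated SVD `D = UΣVᵀ`, every factorization is `C = UΣT⁻¹`,
`S = VTᵀ` for a regular `s×s` transform `T` with all-ones first column.
The **area of feasible solutions (AFS)** is the set of normalized spectral
expansion coefficients `x` (the first row of `T` is `(1, x)`) that can be
completed to a fully nonnegative factorization — the exact picture of the
*rotational ambiguity* of the problem. `mcrafs` provides:

- `factor_core` — truncated SVD, the `T` parameterization, the ε-relaxed
  nonnegativity test (small negative entries up to `ε·max|profile|` are
  accepted, default `ε = 2×10⁻⁴`);
- `afs` — closed-form AFS for two-component systems, adaptive
  boundary-traced polygons for three-component systems, and a brute-force
  grid oracle used to cross-check the tracer;
- `duality` — the complementarity theorem in computable form: a fixed
  spectrum confines the complementary concentration profiles to a line in
  the concentrational AFS (and vice versa); intersecting such lines
  completes a unique factorization from known endpoint spectra plus
  externally measured concentration profiles;
- `bands_closure` — bands of feasible profiles (the profile-space picture
  of the ambiguity) and least-squares scaling by the mass-balance
  (closure) constraint `c₁ + 2c₂ + c₃ = c₀`;
- `rank_annihilation` — an independent cross-check that strips the two
  endpoint components by rank-1 downdates and reads the intermediate off
  the leading singular pair of the residual;
- `kinetics` — hard-model validation: a two-step
  protonation/dimerization scheme propagated in the added-acid coordinate,
  fitted by multi-start least squares;
- `synthetic` — a fully ground-truthed titration generator (12 spectra ×
  401 channels, 200–600 nm, `c₀ = 9.84269×10⁻⁴` mol/l) so every method is
  testable end to end;
- `dataio` / a `mcrafs` command line — delimited-text matrices, JSON AFS
  region files, and subcommands `simulate`, `svd`, `afs`, `duality`,
  `bands`, `annihilate`, `kinetics`.

See `docs/methods.md` for the algorithms, tolerances and known limits.

## Worked example

The standard synthetic titration: a dye is protonated via a dimeric
intermediate; the intermediate is never observed pure and its spectrum
overlaps both neighbors.

```python
import numpy as np
import mcrafs as m

ds, C_true, S_true = m.generate_dataset(m.SyntheticConfig(seed=0))
svd = m.truncated_svd(ds, 3)
print("singular values:", np.array2string(svd.all_singular_values[:5], precision=3))
print("estimated rank:", m.estimate_rank(svd.all_singular_values))

region = m.afs_three_component(svd, "spectral")
print("spectral AFS subsets:", len(region.polygons))

pair = m.complete_factorization(
    svd,
    fixed_spectra=[ds.absorbance[0], ds.absorbance[-1]],   # pure endpoint rows
    fixed_profiles=[C_true[:, 0], C_true[:, 2]],           # e.g. from fluorescence
)
spec = m.ClosureSpec(weights=(1, 2, 1), c0=ds.closure_c0)
scaled, gamma, _ = m.closure_scale(pair.C[:, [0, 2, 1]], spec)
err = np.max(np.abs(scaled @ spec.weights - spec.c0)) / spec.c0
print(f"closure residual (max, relative): {err:.2e}")

res = m.middle_component_by_annihilation(ds, S_true[:, 0], S_true[:, 2], ds.closure_c0)
print(f"rank-1 quality sigma2/sigma1: {res.quality:.2e}")
cos = res.spectrum @ S_true[:, 1] / (np.linalg.norm(res.spectrum) * np.linalg.norm(S_true[:, 1]))
print(f"dimer spectrum cosine vs truth: {cos:.6f}")

model, C_kin, sse = m.fit_kinetics(scaled, ds.conditions, ds.closure_c0, seed=0)
print(f"fitted rates (gauge): k1*c0^2 = {model.k1*model.c0**2:.4f}, "
      f"k2*c0 = {model.k2*model.c0:.4f}")
print("reldiff (max norm):", np.array2string(m.reldiff(C_kin, scaled, "max"), precision=4))
```

prints

```
singular values: [1.968e+01 1.348e+01 2.559e+00 4.530e-04 4.348e-04]
estimated rank: 3
spectral AFS subsets: 3
closure residual (max, relative): 1.18e-05
rank-1 quality sigma2/sigma1: 8.45e-05
dimer spectrum cosine vs truth: 1.000000
fitted rates (gauge): k1*c0^2 = 0.9000, k2*c0 = 0.1000
reldiff (max norm): [5.1610e-06 1.4131e-05 4.8924e-06]
```

Reading the output: three singular values stand far above the noise floor
(three absorbing species). The spectral AFS splits into three isolated
subsets — one per species; the two endpoint species' subsets are tiny
(little ambiguity) while the intermediate's is large. Fixing the two
endpoint spectra and two measured concentration profiles collapses the
ambiguity to a unique factorization whose mass balance holds to ~10⁻⁵
relative after closure scaling. Rank annihilation independently
reproduces the intermediate (`σ₂/σ₁ ≈ 10⁻⁴` says its residual is
essentially rank 1), and the kinetic hard model fits the recovered
profiles with relative errors of ~10⁻⁵, recovering the generating rate
coefficients exactly (in the gauge `k₁c₀² + k₂c₀ = 1`; only the rate
*ratio* is identifiable from titration grades).

The same steps are available from the shell:

```sh
mcrafs --out-dir out simulate
mcrafs --out-dir out svd out/dataset.csv
mcrafs --out-dir out afs out/dataset.csv --side spectral
```

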