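# morebind

Equilibrium analysis of cooperative dimeric protein–DNA binding from
fluorescence anisotropy titrations.

POU-family transcription factors such as OCT2 bind palindromic MORE
("More palindromic Oct factor Recognition Element") DNA sites as highly
cooperative 2:1 homodimers. Quantifying that interaction from anisotropy
titrations is complicated by three things: the labeled probe depletes the
titrant, secondary (oversaturated) complexes add an unsaturable signal on
top of the specific transition, and nonspecific DNA both competes for
protein and — counterintuitively — can *enhance* specific binding at high
salt through intersegmental transfer. `morebind` packages the full
analysis chain for experimentalists working on such systems:

1. **Forward model and fitting** — the observable is

   r = (r_sp·[P]_sp + r_0·[P]_0)/[P]_t + ϕ·[O]

   where the specifically bound probe follows a Hill isotherm in the
   *free* titrant concentration [O] (n_H = 2 for the cooperative dimer),

   [P]_sp/[P]_t = [O]^n / (K_D^n + [O]^n),

   and [O] is obtained at every point by solving the mass balance
   O_t = [O] + n_H·θ·([P]_t + [C]_t) + O_ns over probe, unlabeled
   competitor and a nonspecific lattice. ϕ (M⁻¹) is an empirical linear
   coefficient for excess (supra-dimeric) binding. Fitting is weighted
   nonlinear least squares with multi-start, log-scale positivity,
   curvature-based standard errors and a residual bootstrap.
2. **Salt linkage** — log₁₀K_D is regressed on log₁₀[Na⁺]; the slope (SK,
   association convention) measures net ion release and is decomposed as
   SK = Δm_PE + Δm_other with Δm_PE = ψ·Z from polyelectrolyte theory,
   plus the crossover of two salt series and the per-ion free energy
   ΔG_PE = −ψRT·ln[Na⁺].
3. **Coupled five-species network** — a mass-action simulator (unbound,
   specific, secondary, nonspecific, cross-linked species) with power-law
   salt dependence per transition, validated for thermodynamic cycle
   consistency, reproducing the switch of nonspecific DNA from inhibitor
   (low salt) to stimulator (high salt) of specific-site occupancy.
4. **Synthetic data** — seeded generators for titrations, competition
   experiments and salt series with known ground truth.

The fitting front-ends are scikit-learn-style estimators
(`AnisotropyTitrationModel`, `SaltDependenceModel`) with `fit`/`predict`
and fitted attributes; thin functions (`fit_titration`,
`fit_salt_dependence`, …) wrap them.

## Worked example

```python
import numpy as np
import morebind as mb
from morebind.fitting import confidence_interval

# a synthetic titration: 5 nM probe, true K_D = 3.8 nM, phi = 2.6e4 /M,
# 16 log-spaced points, replicate noise SD 0.002
truth = mb.BindingParameters(kd=3.8e-9, phi=2.6e4, r_specific=0.08)
spec = mb.GeneratorSpec(truth=truth, grid=np.logspace(-9, -5, 16),
                        noise_sd=0.002, seed=7)
fit = mb.fit_titration(mb.generate_titration(spec))
lo, hi = confidence_interval(fit, "kd")
print(f"kd = {fit.params.kd:.3g} M (95% CI {lo:.3g} - {hi:.3g})")

# salt-linkage analysis of the bundled K_D series
res = mb.linkage_analysis(mb.datasets.kd_salt_series())
print(f"SK = {res.sk:.2f} +/- {res.sk_stderr:.2f}")
print(f"dm_pe = {res.dm_pe:.2f}, dm_other = {res.dm_other:.2f}")
```

prints

```
kd = 4.11e-09 M (95% CI 3.79e-09 - 4.46e-09)
SK = -6.92 +/- 0.31
dm_pe = -8.25, dm_other = 1.33
```

The fitted K_D recovers the 3.8 nM truth within its confidence interval
despite probe depletion and the dominant ϕ term. The specific-binding
salt slope SK ≈ −6.9 means roughly seven ions are released per dimer
binding event; polyelectrolyte theory assigns −8.25 of that to DNA
counterion release (ψ = 0.75, Z = −11 contacted phosphates), leaving a
positive protein-side remainder (ion uptake, e.g. lost salt bridges).
Adding the nonspecific-DNA series gives SK = −3.99 and a crossover of
the two salt lines at 0.173 M Na⁺; the five-species network reproduces
the same inhibition-to-stimulation flip (at 0.191 M with illustrative
default constants):

```python
a, b = res, mb.linkage_analysis(mb.datasets.kd_salt_series(True))
mb.crossover_concentration((a.sk, a.intercept), (b.sk, b.intercept))
# 0.173
df = mb.salt_scan(mb.default_network(), np.linspace(0.12, 0.35, 12))
df.attrs["crossover_na"]
# 0.191
```

A `morebind` console command exposes the same pipeline
(`generate`, `fit`, `linkage`, `network`); see `morebind --help`.

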