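# Methods

## Binding model

The saturable observable is modeled as cooperative 2:1 (dimer) binding
of protein O to a single cognate site per probe molecule P,

θ([O]) = [O]^n / (K_D^n + [O]^n),    n_H = 2 by default,

with K_D the half-saturation constant in M. For a Hill coefficient of 2
the macroscopic dissociation constant of the 2:1 complex is K_D², exposed
as `BindingParameters.kd_macroscopic`; all user-facing values stay in M
because that is how the quantity is tabulated and fitted. The anisotropy
of a titration point is the population average over specifically bound
and unbound probe plus an empirical excess-binding term linear in free
titrant, ϕ·[O] (ϕ in M⁻¹). The excess term stands for oversaturated,
supra-dimeric complexes contingent on the specific complex; it is not
given a structural model at the fitting stage.

### Mass balance

The free concentration [O] at each point solves

O_t = [O] + n_H·θ([O])·([P]_t + [C]_t) + N_s·[O]/(K_ns + [O]),

where [C]_t is unlabeled competitor carrying the same site (same K_D and
n_H — it is the unlabeled probe), and the nonspecific lattice is treated
as N_s = (bp total)/(site size) independent Langmuir sites. The default
site size is 14 bp, the approximate footprint of one bound dimer on a
cognate-length duplex, and is configurable; site-overlap (McGhee–von
Hippel) statistics are deliberately out of scope since the data the
package targets do not constrain them. 1.0 unit of poly[d(I-C)] converts
to 7.0 mM bp (`morebind.io.POLY_DIC_BP_PER_UNIT`).

The balance residual is strictly increasing in [O], so the root is
unique and bracketed in [0, O_t]; it is found by Brent's method at
machine-precision tolerances and verified to satisfy the balance to
1e-15 + 1e-10·O_t mol/L. A multivariate solver is unnecessary after
substituting the isotherms into the conservation equation.

Titrant sequestered in ϕ-type secondary complexes is *not* subtracted by
default: the probe is nM against μM titrant, so the correction is far
below noise. An opt-in flag (`deplete_secondary`) adds a 1:1 accounting
in which excess anisotropy is converted to protein equivalents through
(r_sp − r_0) per probe; because the stoichiometric interpretation of ϕ
is not experimentally pinned down, this flag is a sensitivity-analysis
device, not part of the standard model.

## Titration fitting

`AnisotropyTitrationModel` minimizes Σ wᵢ(r_obs,i − r_pred,i)² with
Levenberg–Marquardt. K_D and ϕ are optimized as log₁₀ values so
positivity is structural; r_sp (and optionally r_0) are linear. Defaults:
free = (kd, phi, r_specific); n_H fixed at 2 (freeable for diagnostics);
r_0 fixed at 0 because the supported data are baseline-subtracted.
Weighting is unweighted by default, inverse-variance optional (with
equal SDs the two coincide; a unit test enforces this). Five
deterministic starts spread log₁₀K_D over the data range; best RSS wins,
first index breaking ties. At least 6 points are required.

Uncertainty: the covariance is s²(JᵀJ)⁻¹ evaluated by SVD pseudo-inverse
(near-singular directions get large finite variances instead of a failed
inversion), mapped to the natural scale by the delta method.
`confidence_interval` builds Wald intervals on the log scale for log
parameters with Student-t quantiles at the residual degrees of freedom.
A fit is flagged unconverged when the optimizer fails, the Jacobian is
numerically rank-deficient (singular-value ratio < 1e-6, e.g. a flat
curve), or the optimum violates a parameter invariant.
`bootstrap_uncertainty` resamples fit residuals (≥ 200 replicates),
refits from the optimum with a single start, and reports percentile
intervals; on simulated data it agrees with the curvature-based errors
within a factor of ~2.

## Salt linkage

log₁₀K_D is regressed on log₁₀[Na⁺] by ordinary least squares (the
regression oracle in the tests is the closed-form normal-equations
solution). SK is returned as the *negative* of the slope so net ion
release appears as SK < 0 (association-constant convention). Unweighted
regression is the default: it reproduces the +nonspecific-DNA series
slope (−4.0) exactly from the tabulated cells and the specific series
within its quoted error (−6.9 computed vs −6.8 ± 0.3; the 0.1 gap traces
to rounding of tabulated K_D values and/or an unstated weighting in the
original fit). The decomposition Δm_other = SK − Δm_PE holds exactly by
construction; Δm_PE = ψ·Z with ψ an input (0.75 default, the end-effect
corrected value for a 20 phosphate-pair oligonucleotide; ψ_∞ = 0.88 for
polymeric B-DNA is provided as a constant). Z is a signed contact count
supplied by the user (−11 for the dimer studied here); the package does
not parse structures to count contacts. Summary displays round
half-away-from-zero (−8.25 → −8.3) to match table conventions.

The crossover of two series solves the two log-linear lines in closed
form; an `ExtrapolationWarning` is raised when the intersection falls
outside a supplied data range. ΔG_PE = −ψRT·ln[Na⁺] uses
R = 8.314 J mol⁻¹ K⁻¹ and reports kJ/(mol ion).

## Coupled five-species network

Species: (1) unbound protein, (2) specific dimer complex, (3) secondary
complex = (2) plus one extra protein (the open-ended "one or more" is
fixed at one, extensible through custom compositions), (4) nonspecific
complex (one protein per lattice site), (5) cross-linked intermediate =
(2) plus a protein bridging one nonspecific site. Transitions carry an
ion stoichiometry dm; K(Na⁺) = K_ref·(Na/Na_ref)^dm. Consistency —
element balance per reaction, and existence of per-species formation
potentials reproducing both ln K and dm (equivalent to unit cycle
products and zero cycle dm at every salt) — is validated before any
solve; formation constants are then recovered by least squares and the
three conservation equations are solved on log free concentrations by a
damped fixed point followed by a Newton polish, to relative residuals
≤ 1e-10.

Default parameterization: dm(1→2) = −6.8 (the measured specific-binding
slope, attached in full to the single mass-action edge),
dm(4⇌5) = dm(3⇌2) = 0 (no net change in DNA occupancy), nonspecific
binding more salt-sensitive than specific (dm(1→4) = −9), and cycle
closure then forces ion uptake dm(5→3) = +9. K_ref magnitudes for edges
touching species 3–5 are not measured anywhere; the defaults
(K_ns = 1e4 M⁻¹, K_bridge = 5e8 M⁻¹, K_extra = 2e4 M⁻¹ at 0.175 M) are
illustrative values chosen inside the open parameter region where
nonspecific DNA inhibits specific occupancy at low salt and stimulates
it at high salt, with the sign change landing near the experimentally
observed 0.175–0.2 M window (the default scan flips at ≈ 0.19 M). The
module is a qualitative/semiquantitative simulator of the compensation
mechanism, not a fitted model. Two ablations characterize the mechanism:
removing the bridged intermediate leaves pure inhibition at all salts,
and a salt-independent network (all dm = 0) has a single-signed effect.

## Synthetic data

The generator mirrors the assay design: 5 nM probe, titrant grids
defaulting to sixteen 2-fold dilutions from 1 μM (log-spaced grids
1 nM–10 μM are used for parameter-recovery studies so the highest K_D
values stay bracketed), three replicates, homoscedastic Gaussian noise
with SD 0.002 anisotropy units (matching roughly uniform replicate error
bars; heteroscedastic noise is not modeled). Replicate means and sample
SDs are reported; everything is deterministic given the seed. Salt
series follow kd(na) = kd_ref·(na/ref)^(−SK) with optional lognormal
jitter. A warning fires when the design grid does not come within 10×
of the true K_D.

What passing synthetic tests do *not* show about real data: real
titrations can carry correlated drifts, intensity artifacts of the
label, pipetting-scale errors on the concentration axis and
heteroscedastic noise, none of which are simulated; parameter-recovery
rates here are therefore best-case.

## Problem sizes and numerical checks

The test suite cross-checks the speciation solver against an independent
200-iteration bisection oracle on 1000 random parameter draws (≤ 1e-12
relative), closes noiseless generate→fit loops to 1e-6 relative,
verifies Wald-interval calibration over 200 seeded noisy repeats at
K_D ∈ {1, 3.8, 30, 1200} nM (observed coverage ≥ 90% at nominal 95%),
checks the network solver against a brute-force 10⁶-point grid plus a
closed-form 1:1 oracle, and validates noise calibration over 10⁴ draws.
Monte-Carlo sizes were chosen to make the checks statistically
meaningful while keeping the default suite in the minutes range.

## Known limitations

- The competitor is assumed identical to the probe site; heterologous
  competitors would need their own constants.
- Nonspecific binding uses independent non-overlapping sites; occupancy
  of a true lattice at high loading is overestimated.
- ϕ is empirical; converting it to a species population requires
  assumptions the data do not constrain.
- Saturating-competitor suppression of probe binding is limited by the
  titrant-to-capacity ratio (≈ 5% residual saturation at a 1 μM titrant
  top against 10 μM competitor), not arbitrarily complete.
- The network module's unmeasured constants are order-of-magnitude
  choices; only directions (signs of dm, the existence and approximate
  position of the sign flip) are meaningful.
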