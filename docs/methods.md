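# Methods

## Structural model

Doxycycline disposition in pigs is described by a mammillary
three-compartment model: a central (plasma) compartment with volume Vc
exchanging with two peripheral compartments (V2, V3) through
distributional clearances Cl2 and Cl3, and elimination (clearance Cl)
from the central compartment only. All parameters are per kilogram
(L/kg, L/kg/h) and all doses doxycycline base in mg/kg, so absolute body
mass never enters the engine; `salt_to_base_factor` converts hyclate,
monohydrate and hydrochloride label doses.

Oral administration adds a depot compartment with first-order absorption
rate Ka and absolute bioavailability F. Four oral submodels share the
systemic disposition but have their own (Ka, F): in-feed under field
conditions (group-fed animals, slow and highly variable absorption,
Ka = 0.072/h, F = 0.501), in-feed under laboratory conditions
(Ka = 0.144/h, F = 0.340), solution in drinking water (Ka = 0.689/h,
F = 0.307) and solution by stomach tube (Ka = 0.725/h, F = 0.258).

### Closed-form solution

The disposition rate matrix of a mammillary model with positive
parameters has three real, negative, distinct eigenvalues, so profiles
are tri-exponential (IV bolus) or quadri-exponential (first-order
input). `conc_profile` eigendecomposes the 3×3 (IV) or 4×4 (oral) system
once per parameter set and superposes per-dose modal solutions; doses
enter linearly and profiles are time-shift invariant. Numerical
safeguards:

- eigenvalue spacing below 1e-9 relative falls back to stepwise matrix
  exponentials (unconditionally stable, slower);
- an absorption rate colliding with a disposition eigenvalue is a
  removable singularity: Ka is perturbed by 1e-7 relative with a warning.

The closed form is verified against an adaptive-step ODE oracle to a
relative error below 1e-6 wherever the concentration exceeds one
millionth of the peak; below that level the oracle's own roundoff floor
(absolute ~1e-12 of the peak after thousands of steps) dominates, which
is why the comparison denominator is floored there.

### Secondary parameters

Terminal half-life is ln 2 over the smallest-magnitude disposition
eigenvalue; Vss = Vc+V2+V3; MRT_iv = Vss/Cl; MAT = 1/Ka; the
steady-state daily exposure is AUC = F·D/Cl. Note that the
"one-compartment limit" of the terminal half-life requires the
peripheral compartments to vanish in both clearance and volume: with
volumes held fixed, the slow near-zero eigenvalue persists (with
vanishing residue), and the eigenvalue-based half-life diverges rather
than reducing to ln2·Vc/Cl.

A known inconsistency in the published parameter table is documented
rather than resolved by guessing: the 50-kg column prints V3 = 0.376
L/kg, which is the covariate exponent of V3, not a volume, and breaks
the power-model pattern of the 10/50/100-kg columns (0.295 → 0.536 →
0.699). This package uses V3 = 0.536 L/kg at the 50-kg reference.
Likewise the printed 50-kg Vss (1.21 L/kg) is internally consistent with
the printed MRT but not with Vc+V2+V3; neither is used as a check value.

## Covariate model

Body weight enters as a power model on Cl (exponent 0.299), Cl2
(−0.224), Cl3 (−0.544) and V3 (0.376), referenced to 50 kg (the
population median is ≈44 kg; 50 kg is the fixed scaling point). The
reference identity — scaling at BW = 50 returns the typical value
exactly — is asserted in tests. A binary health-status covariate
(healthy/sick) is supported as an exponential effect on F; it carries no
effect in the shipped final model, matching the finding that health
status was not significant.

## Population model

Between-subject variability is exponential: an individual parameter is
the covariate-scaled typical value times exp(η), η ~ N(0, ω²), with a
diagonal ω matrix (no published correlations; documented assumption).
Published BSV figures are CV percentages; the default transform is the
lognormal identity ω = sqrt(ln(1+(CV/100)²)), with the direct reading
ω = CV/100 available as an alternative convention (the source does not
state which it used; for the PK/PD cutoff results below the conclusions
are robust to either choice). Individual bioavailability F·exp(η) may
exceed 1 and is deliberately not truncated (no truncation is described
for the source analysis); a `cap_f_at_1` switch exists for sensitivity
analysis.

Residual error is additive plus proportional per route,
SD(f) = sqrt(stdev0² + (cmult·f)²), with route-specific magnitudes (the
field in-feed arm is the noisiest: stdev0 = 0.113 µg/mL, cmult = 0.228).

## Estimation

The marginal likelihood of the nonlinear mixed-effects model is
approximated per subject by the Laplace method: the joint negative log
density is minimized over the subject's etas (warm-started BFGS), and
the log-determinant of the finite-difference Hessian at the mode is
added. The approximation is exact for models linear in η (unit-tested
against the conjugate-normal closed form) and reduces to the pooled
extended-least-squares −2LL when all omegas are zero. OFV is −2·Σ log
marginal likelihood; AIC = OFV + 2·(number of estimated parameters).

Fixed effects are optimized on the log scale (bound-constrained to
[1e−4, 1e3] times the starting value) with derivative-free simplex or
Powell search; covariate exponents and the health effect stay linear in
[−5, 5]. Fitting is staged as in the source workflow: disposition and
its BW exponents from the IV data alone; then, with the IV fixed effects
frozen at their optimum, the oral (Ka, F) and residual terms with all
random effects re-estimated jointly. This reproduces the staged design
at the level of estimates, not engine internals — the reference
implementation's FOCE-ELS/QRPEM algorithms are proprietary and no
bit-compatibility is claimed.

Observations below the LLOQ are discarded before fitting (as in the
source analysis, where they were 2% of samples); no censored-likelihood
handling.

- **Covariate search**: every subset of the six disposition parameters
  may receive a BW exponent — 2⁶ = 64 scenarios including the empty
  base model. Subsets improving AIC by ≥6.635
  (the χ²₁ p<0.01 equivalent) are flagged; AIC ties break toward the
  smaller subset. The candidate list is restrictable to keep small
  studies tractable.
- **Bootstrap**: subjects resampled with replacement, stratified by
  route, each resample the size of the original; percentile 2.5/97.5%
  intervals; aborts if more than 20% of refits fail. A covariate is
  declared significant when its 95% CI excludes zero. Standard errors
  come from the bootstrap only (no information-matrix SEs).
- **Shrinkage**: η-shrinkage 100·(1−SD(EBE)/ω) per parameter;
  ε-shrinkage 100·(1−SD(IWRES)).
- **VPC**: each subject's design simulated n times (default 500);
  observed quantiles (10/50/90 or 20/50/80) per time bin compared with
  the simulated quantile median and 95% band; empty bins merge with a
  neighbor.
- Inits default to the base model's values; NCA-derived Cl/Vss make
  sensible starting points for real data. Seeds are explicit arguments
  everywhere; there is no global RNG state.

## PTA and PK/PD cutoffs

For each scenario (daily dose, body weight, oral submodel) 5000
individuals are drawn from the population model at the fixed body
weight. Because the model is linear, each individual's steady-state
index has the closed form

    fAUC/MIC = fu · F_i · D_daily · n_days / (Cl_i · MIC)

with fu = 0.31 fixed (fu variability deliberately excluded — including
it would bias the cutoff downward without affecting free
concentrations). A numerical mode (trapezoidal integration of a
superposed multi-dose profile after ≥10 terminal half-lives of loading)
cross-checks the closed form to <0.5%. Residual (assay) error is
excluded from PTA by default: the simulated quantities are
model-predicted curves, not noisy observations; a switch includes it for
sensitivity analysis. Steady state is computed analytically, not by
simulating loading days.

PTA per MIC is the fraction of individuals with fAUC/MIC ≥ 72 h over 3
days (24 h/day, the classical bacteriostatic target; the murine-derived
alternative of 12.36 h/day is exposed as a config option, not the
default). The PK/PD cutoff is the highest grid MIC with PTA ≥ 0.90,
equivalently the highest MIC whose 10th percentile (Q10) of fAUC/MIC
still reaches the target. At n = 5000 the Monte Carlo standard error of
a PTA near 0.9 is ≈0.4 percentage points.

Only Cl and F enter the index, so the simulation draws their BSV
(27.1% and route-specific, e.g. 84.8% for in-feed field conditions);
the remaining disposition BSVs do not affect fAUC and are irrelevant to
the cutoff under this model.

**Reproducibility of the published contrast.** With the shipped
parameters this package reproduces: cutoff 0.25 mg/L at 20 mg/kg/day for
10-kg animals both in feed and in drinking water, and failure of the
50-kg drinking-water scenario to reach 0.25 mg/L. The further published
claim that the in-feed cutoff of 0.25 mg/L holds regardless of body
weight is *not* reproducible from the printed parameters under the
documented diagonal-ω lognormal reading: at 50 and 100 kg the in-feed
PTA at MIC 0.25 falls to ~0.8 and ~0.73, putting the cutoff at
0.125 mg/L. The discrepancy is surfaced here rather than resolved by
altering parameters; the 10-kg scenarios, which are reproducible, anchor
the checks.

## Synthetic data

`generate_trials` emulates the source meta-analysis structure: 380
profiles in 11 trials — 57 rich single-dose IV, 215 sparse in-feed field
profiles (2×5 mg/kg 12 h apart; a pre-second-dose trough at 12 h then
samples to 24 h, with a 41-animal subset sampled at 36 h), 50 in-feed
laboratory data sets (including a bioequivalence trial whose 11 animals
were dosed on two occasions), 30 drinking-water and 28 stomach-tubing
profiles — totalling ≈3300 observations. Body weights follow a segmented
log-uniform distribution (half the mass on [8.5, 44] kg, half on
[44, 101] kg), covering the full piglet-to-adult range with median
exactly 44 kg. Sex and health labels are generated in the documented
proportions but carry no effect, matching the final model.

Per-trial assay LLOQs span 0.025–0.2 µg/mL, and each trial's follow-up
is truncated where the typical profile approaches its assay's LLOQ — as
the real 12–48 h protocols were — which is what yields the documented
~2% below-LLOQ fraction; `censor_lloq` removes those observations and
reports the fraction.

What the generator does *not* emulate: assay drift and day effects,
inter-occasion variability, the real trials' exact individual doses and
missing-sample patterns, or η correlations. Passing recovery tests on
these data therefore demonstrate correctness of the estimation machinery
under the stated model, not robustness to real-data misspecification.

## Problem sizes in the test suite

Fitting a nonlinear mixed-effects model is expensive, so the test suite
runs deliberately scaled-down studies, chosen as the package's own
defaults for routine verification: recovery harnesses use 20 rich IV
subjects and 120 sparse field subjects (vs 57/215 in the full design)
with BSV restricted to the parameters that drive the quantities under
test (Cl, Vc, F); bootstrap and covariate-search checks use 10–24
subjects with fixed-effect-only fits. The full-size generator remains
the default for `make-synthetic` and is exercised for structure (counts,
body weights, censoring fraction) rather than refitting. Monte Carlo PTA
checks run at the full n = 5000.

## Known limitations

- Laplace, not adaptive Gaussian quadrature: small bias is possible for
  very sparse designs with large ω (the field-trial arm approaches
  this); the recovery tests bound the practical effect.
- Diagonal ω only; no inter-occasion variability; no saturable kinetics,
  infusion input or absorption lag (none are modeled in the source).
- NCA is for rich designs; sparse-design trapezoidal bioavailability is
  biased by design and intentionally unsupported.
- The ECOFF/clinical-breakpoint adjudication that consumes these cutoffs
  is out of scope: the package computes PK/PD cutoffs only.
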