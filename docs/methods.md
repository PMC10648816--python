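# Methods

This note records the models, conventions and numerical choices behind the
package, and what its synthetic-data tests do and do not demonstrate.

## Measurement model and QC

A liver QUS exam yields repeated per-site readings per modality. The
aggregation rules are the standard clinical ones, applied post hoc:

| modality | value | quality metric | validity rule | extra rule |
|---|---|---|---|---|
| TAI | AC, dB/cm/MHz | fit-R² ∈ [0,1] | R² ≥ 0.6 | — |
| TSI | BSC-D, a.u. | none | — | — |
| SWE | LS, kPa | RMI ∈ [0,1] | RMI ≥ 0.4 | IQR/median < 0.30 |

All modalities require at least five valid readings; the aggregate is their
arithmetic mean (all valid readings are used, not only the first five).
Quartiles for the IQR use linear interpolation between order statistics
(numpy's default, "type 7"); the convention is fixed so the 30 % dispersion
rule is reproducible. Quality thresholds are inclusive (a reading at exactly
R² = 0.6 is valid), matching the convention that discards strictly
sub-threshold readings. Whether invalid acquisitions were re-measured in the
clinic is unknowable post hoc; only the post-hoc rules are enforced.

## Grading

Steatosis: S0 <5 %, S1 5–10 %, S2 10–20 %, S3 ≥20 % MRI-PDFF. Fibrosis by
the elastography "rule of four": F2 ≥5, F3 ≥9, F4 ≥13 kPa. All cuts are
lower-inclusive, consistent with the ≥-style dichotomies used for the
classification tasks, so dichotomizing at 5 % equals (grade ≥ S1).

## Calibration model

The single-predictor law is `y = β₁·exp(β₂·x) + β₃` with y = MRI-PDFF (%)
and x one QUS parameter. The combined model is the additive two-exponential
with a shared offset,

    y = β₁·exp(β₂·AC) + β₃·exp(β₄·BSC-D) + β₅,

chosen so each predictor's marginal shape equals its single-predictor law
and the single-AC model is nested inside (β₃ = β₄ = 0). Five free
coefficients is the smallest additive form with that property. The UEFF is
this model's prediction, never clipped: negative estimates for fat-free
livers are informative output and are preserved through CSV round-trips.

### Fitting

- Optimizer: scipy trust-region-reflective least squares with adaptive
  (`x_scale="jac"`) scaling — the AC and BSC-D exponents differ by ~two
  orders of magnitude.
- Convergence: relative SSE change < 1e-10 (scipy's `ftol` test) or 500
  iterations (as a function-evaluation budget of 500·(p+2)); both recorded
  in `fit_meta`, plus an absolute near-zero-SSE escape because a purely
  relative test can never fire on an exact fit.
- Start values, single model: β₃ ← min(y) − 1e-3; β₂ ← OLS slope of
  ln(y − β₃ + 1e-6) on x; β₁ ← exp(intercept). Deterministic and cheap; the
  log-linearization is exact when the model is exact.
- Start values, combined model: deterministic multi-start — (1) backfitting
  (AC-only fit, then an exponential fit of its residuals on BSC-D), (2) the
  AC-only fit with a null BSC-D term, (3) independent log-linearizations
  with halved amplitudes. Best SSE wins. The additive two-exponential has a
  plateau of local optima where a near-zero rate imitates a linear term;
  multi-start plus the nested AC-only floor makes the result reproducible
  and never worse than the single-predictor fit.
- Rate bounds: the exponent is constrained so the exponential term spans at
  most e⁸ across the observed predictor range. A saturating tissue law uses
  one or two e-folds; without the cap, noisy five-parameter fits drift to
  single-point spike solutions (rate ≈ 40, amplitude ≈ e⁻⁴⁰) that explode
  on external cohorts. The cap encodes physics, wide of any plausible fit.
- Degenerate inputs: a constant predictor raises immediately (the rate is
  unidentifiable); near-collinear AC/BSC-D columns are fitted but flagged
  `ill_conditioned` in the metadata.

### Diagnostics

R² = 1 − SSres/SStot; adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) with
p = number of QUS predictors (1 or 2), not raw coefficient count — the
penalty tracks independent variables; RMSE = √(SSres/n). On external data
both R² variants may be negative and are reported unclamped.

## Validation

Three-fold cross-validation repeated five times: per repeat a fresh seeded
shuffle partitions the cohort into k near-equal disjoint folds (sizes differ
by ≤1); the model is refitted on k−1 folds and scored on the held-out fold;
the summary is the mean and sample SD (n−1) over all 15 fold values. Folds
are not stratified by grade. Non-convergent folds would be excluded with a
warning and counted, never silently dropped. External testing applies the
frozen model — no refit — and reports diagnostics plus the Pearson
correlation between prediction and observed MRI-PDFF.

## Statistics

- Pearson ρ with the Fisher-z interval tanh(atanh ρ ± z₀.₉₇₅/√(n−3)) and a
  two-sided t-test (n−2 df). |ρ| = 1 yields the degenerate CI (ρ, ρ).
- The sub-range scan searches all contiguous intervals with endpoints at
  observed values containing at least a configurable fraction (default ½)
  of records, and returns the interval maximizing ρ, ties to the widest.
  How the strongest sub-range "should" be found is not canonical; an
  exhaustive scan with a minimum-mass constraint is this package's explicit,
  exploratory choice — maximizing over intervals biases ρ upward, so scan
  results are descriptive, not inferential.
- Linear screens are ordinary least squares (statsmodels), one univariable
  fit per predictor plus one joint fit; the joint rows share the model-level
  adjusted R² and F.
- Kruskal–Wallis H is tie-corrected (scipy); Dunn's pairwise z uses the
  tie-corrected pooled variance of mean ranks with two-sided p-values, and
  Holm's step-down adjustment (with the running-maximum enforcement that
  makes adjusted p monotone in raw p). All-equal samples are H = 0, p = 1 by
  convention.

## Diagnostics (ROC)

AUC by the Mann–Whitney identity (ties ½), CI from DeLong's placement-value
variance, bounds clipped to [0, 1]. Cutoff candidates are midpoints between
adjacent distinct scores plus ±∞; the classification rule is
score ≥ cutoff ⇒ positive; ties in Youden's J break toward the higher
cutoff (higher specificity). J = TPR − FPR is the standard index; a literal
J = TPR − FNR = 2·TPR − 1 variant is kept behind `j_definition="literal"`
for auditing sensitivity-only threshold choices, which cannot trade
sensitivity against specificity and is therefore not the default. Power for
the two-sided test of AUC = 0.5 uses the Hanley–McNeil variance at the null
and at the observed AUC; "adequate" means type-2 error below 10 %.
Predictive values with an empty predicted class are NaN by convention.

## Synthetic cohorts

The generator emulates the joint structure the analysis assumes, not any
patient's data:

- **Grade mix** fixes band counts by largest-remainder rounding (so the
  default n = 90 mix (0.211, 0.244, 0.378, 0.167) gives exactly
  19/22/34/15); fat fraction is uniform within its band, the severe band
  truncated at 45 %.
- **AC link**: PDFF = a₁·exp(a₂·AC) + a₃, inverted to produce AC from the
  noiseless fat fraction. Defaults (4.0535, 2.1562, −12.270) were calibrated
  once by least squares against published cohort anchors (AC 0.55–1.22
  dB/cm/MHz spanning PDFF ≈ 1–44 %); they are package fixtures.
- **BSC-D link**: BSC-D = c₁ + c₂(1 − exp(−c₃·PDFF)), defaults
  (84.589, 27.343, 0.0758) calibrated the same way; BSC-D is modelled as a
  function of fat (not the reverse) to encode its stronger saturation.
- **Noise**: observed PDFF = true + N(0, 6 %) clipped at zero; BSC-D noise
  N(0, 6 a.u.). The 6 % default reproduces the dispersion scale of
  published cross-validation errors (~6.4 % RMSE) and strong-but-imperfect
  UEFF–PDFF correlation; it was fixed before any downstream result was
  inspected.
- **Liver stiffness** is log-normal (parameterized by arithmetic mean/SD:
  7.24 ± 3.2 kPa training-like, 11.26 ± 8.9 external-like) and statistically
  independent of fat; **BMI** is normal plus 2.5 kg/m² per log1p(% PDFF).
- All draws flow from one seed sequence with one child stream per variable.

What passing tests on these cohorts show: the estimators, the harness and
the pipeline are correct on data with the assumed structure. What they do
not show: performance on real livers — the generator has uniform-in-band
fat (real cohorts cluster), Gaussian noise (real QUS error is
heteroscedastic and operator-dependent), exact link laws, and no
vendor/site effects.

### A note on coefficient recovery under realistic noise

With n = 90 and 6 % measurement noise, the three coefficients of the
exponential law are individually ill-determined even though the fitted
curve is excellent: the Fisher-information (Cramér–Rao) bound at the default
design puts the per-coefficient relative sampling SD at ≈0.83/0.27/0.65,
so median relative errors of ~0.5/0.2/0.45 are the statistical floor, not an
optimizer deficiency. The parameters trade off along a ridge (a larger rate
with a smaller amplitude and shifted offset produces a nearly identical
curve over the observed AC range). Curve-level quantities — predictions,
RMSE, R², AUC — are stable; coefficient-level agreement should only be
expected from noiseless data.

## Problem sizes

Defaults throughout — n = 90 training and n = 51 external cohorts, 15
cross-validation folds, 100 replicate cohorts for recovery studies, 1000
binormal simulations for interval coverage, 20 replicates per noise level
for monotonicity checks — are the package's chosen simulation sizes: large
enough for stable Monte-Carlo summaries at the reported precision.

## Known limitations

- The combined model's cross-validated performance has heavy-tailed spread:
  with five coefficients on ~60-point training folds it occasionally fits a
  poor fold, mirroring the high fold-to-fold SD expected of such models.
- The sub-range scan is O(n²) intervals × O(n) per correlation; fine for
  clinical n, not for thousands of records.
- DeLong intervals undercover slightly (~93–95 %) at 30 + 30 observations;
  this is a known small-sample property of the estimator.
- The generator's links are identifiable fixtures, not fitted patient data;
  absolute numbers produced on synthetic cohorts characterize the method,
  not any clinical population.
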