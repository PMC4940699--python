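# Methods

This note documents the models, rules and numerical choices implemented in
`ckdval`, in the order data flows through the pipeline.

## Synthetic cohort generator

The generator emulates a deprived urban UK primary-care population
observed through linked EHR tables. Per patient it draws:

- **Demographics.** Age at entry ~ Normal(42.7, 17.3²) truncated at 18;
  female fraction 0.519; ethnicity missing with probability 0.356 and
  otherwise 90 % White / 9 % other / 1 % Black; deprivation (Townsend-like)
  ~ Normal(1.6, 3.4²) with 1.9 % missing.
- **Comorbidity codes** as Bernoulli flags at configurable prevalences
  (hypertension 14.5 %, type-2 diabetes 3.7 %, cardiovascular disease
  7.8 %, …), dated before the entry window; a configurable fraction of
  diabetes codes is emitted untyped, with dates consistent with the
  age-35 typing rule so the phenotyper can be exercised on it.
- **Repeat prescriptions**: two scripts inside the 6-month pre-entry
  window (antihypertensives 14.4 %, NSAIDs 3.1 %, lithium/calcineurin
  inhibitors rare).
- **Laboratory series.** Each patient has a latent linear eGFR trajectory
  `baseline + slope·t` with baseline ~ Normal(83.7, 9.4²) mL/min/1.73 m²
  and measurement noise SD 3; serum creatinine is back-computed by
  inverting the MDRD equation so both analytes are mutually consistent.
  Pre-entry labs (creatinine, haemoglobin, BMI, blood pressures, HDL,
  smoking category) are emitted with one minus the configured missingness
  fraction (SBP 49.3 %, haemoglobin 71 %, …); post-entry creatinine is
  measured ~1.2 times/year until death, move-out or study end.
- **Outcome mechanism.** A latent logistic model on the generated
  covariates (intercept −3.7; age +0.045/year centred at 45; comorbidity
  effects 0.3–0.85) defines each patient's true 5-year risk. Patients
  drawn as "progressors" receive a slope that crosses eGFR 57 at a uniform
  time within the horizon; non-progressors drift at −0.3 ± 0.3 per year.
  60 % of progressors additionally receive a CKD stage 3–5 code 30–365
  days after the crossing, and a small code-only rate (0.2 %) exercises
  the diagnostic-code arm alone. The intercept was chosen so the realized
  event prevalence lands near 3–5 %, the range typical of general-
  population CKD incidence over five years; the age–risk gradient is a
  free parameter, not calibrated to any particular locality.
- **Vital status.** Death hazard 0.02/year at age 70, log-linear in age
  (+0.08/year); move-out 1.2 %/year.

Entry anchors are exponentially distributed over the entry window (mean 60
days from its start), matching the early-contact skew of real registries;
all pre-entry events are dated before the window start, which makes each
patient's anchor their first in-window record. A consequence mirrored from
real data: patients anchored deep into the window cannot carry an
observable repeat-prescription flag, because the 6-month medication window
ends before the window starts.

A single integer seed expands into fixed, named substreams (demographics,
codes, prescriptions, labs, outcome, vital status), so adding a table
leaves the others bit-identical.

**What the generator does not emulate:** realistic code vocabularies,
practice-level clustering, informative measurement timing (sicker patients
measured more often), non-linear eGFR trajectories, and correlated
comorbidity structure beyond what the latent risk model induces. Passing
tests on this cohort therefore demonstrates correctness of the pipeline's
rules and estimators, not transportability of any conclusion to real EHR
data.

## Phenotyping

- **eGFR**: 4-variable IDMS-traceable MDRD
  (175 · Scr⁻¹·¹⁵⁴ · age⁻⁰·²⁰³ · 0.742[female] · 1.212[Black]) and the
  2009 CKD-EPI creatinine equation (κ = 0.7/0.9, α = −0.329/−0.411,
  constants 141, 0.993, 1.018, 1.159).
- **CKD onset (main rule)**: at least two *consecutive* eGFR values < 60
  spanning ≥ 90 days, or a CKD stage 3–5 code. "Consecutive" means
  adjacent in time with no intervening value ≥ 60; the span is measured
  first-to-last within one sub-60 run. The onset date is the date the
  criterion is first satisfied — the confirming measurement or the first
  code — a prediction-time-consistent convention. Same-day duplicate labs
  keep the day's lowest eGFR (deterministic, conservative). Calendar
  arithmetic uses 90/182/365 days for 3/6/12 months.
- **Cohort rules**: adults (≥ 18) with ≥ 1 record in the entry window;
  entry = first in-window record; prevalent CKD (criterion satisfied on
  strictly pre-entry data) excluded; follow-up to the earliest of study
  end, death, move-out, onset. Death before CKD censors in the main
  analysis (none of the validated models handle competing risks) and is
  recoded as an event at the death date in the death-as-event variant.
  `complete_followup` = developed CKD or observed ≥ the horizon; the
  fixed-horizon (logistic/score) validations run on this subset, Cox
  c-indexing additionally on everyone.
- **Predictors at entry**: comorbidity = any code strictly before entry;
  medication = ≥ 2 prescriptions in the prior 6 months; lab = most recent
  value in the prior 12 months (the entry-day record itself is excluded);
  untyped diabetes assigned type 1 if the first diabetes code predates age
  35; anaemia = haemoglobin < 13 g/dL (men) / < 12 g/dL (women), the WHO
  convention; missing ethnicity defaults to White British (> 90 % of the
  emulated population).

## Imputation

Chained equations, 10 imputations × 10 cycles (both configurable; the two
numbers are deliberately decoupled because "10 iterations" alone does not
pin down the chained-equations geometry). Continuous variables use
Bayesian-perturbed linear fits with predictive mean matching (5 donors),
binary variables logistic posterior draws; a failed conditional fit falls
back to an unconditional draw from the observed margin with a warning. The
imputation model includes age, sex and the fixed-horizon outcome indicator
alongside the incomplete predictors. Metrics are computed per completed
dataset and averaged; bootstrap confidence intervals come from the first
completed dataset, so Rubin's-rules variance pooling is intentionally out
of scope.

## Model registry

A model is data: family (logistic | cox | score), terms (predictor,
transform, coefficient or integer points), intercept or baseline survival
at the horizon, optional centering constant LP̄ and development summary.
Transforms cover identity, centering, log, fractional-polynomial powers,
category indicators and threshold/band conditions — enough to express the
published models' printed forms, including fractional-polynomial age terms.
Conventions:

- LP excludes the intercept; risks are `expit(β₀ + LP)` (logistic) and
  `1 − S₀(h)^exp(LP − LP̄)` (Cox, LP̄ defaulting to 0 when a publication's
  centering is unstated).
- A logistic model without a published intercept derives it from the
  development summary: `β₀ = logit(π) − Σ βx̄` (the mean-covariate
  approximation); by construction, predicting at x̄ then returns π
  exactly, which the tests assert to machine precision.
- Development summaries are recorded on the *transformed* scale (mean of
  the transformed covariate, prevalence of the condition), so the
  summary-based mean linear predictor is a plain dot product and agrees
  exactly with the individual-level mean for additive terms.
- Models are applied at their published horizon's coefficients to the
  5-year outcome without rescaling, exactly as an external validation of
  the printed formulas would.
- Predictors unavailable in the validation data (e.g. proteinuria, 95 %
  missing) are marked `dropped: true` and contribute nothing.

## Validation metrics

- AUC in Mann-Whitney form (ties ½) and Harrell's c (pair comparable iff
  the earlier time is an event; score ties ½), checked against brute-force
  enumeration in the tests.
- MAPE = mean |p − y| with its SD; for a perfectly calibrated model this
  converges to E[2p(1−p)], which the parameter-recovery test asserts.
- Calibration slope = coefficient b of the logistic recalibration fit
  logit P(y=1) = a + b·LP, with a Wald 95 % CI; for Cox models the same
  logistic fit is applied to the binary 5-year outcome on the
  complete-follow-up cohort. 10 quantile calibration groups by default.
- Thresholds classify `value ≥ t` positive everywhere (risks and integer
  scores alike); Youden's threshold maximizes J = sens + spec − 1 over
  observed values, ties broken toward the lowest threshold (a 10⁻⁹ slack
  absorbs float noise in the tie comparison).
- Net benefit NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) on a grid
  p_t = 0.01…0.99 step 0.01, with treat-all and treat-none reference
  curves.
- Top-decile capture: threshold at the 90th percentile of predicted risk;
  proportion of all observed cases at or above it.
- Percentile bootstrap, patient-level resampling, B = 500, seeded;
  resamples with a single outcome class are redrawn. Threshold-metric SDs
  are bootstrap standard errors (B = 200 by default).

## Pipeline

`run_validation` wires the stages together per cohort variant (all,
complete-follow-up, NICE risk-factor subgroup, complete-case) and writes
per-model long-format reports, combined discrimination/threshold/case-mix
tables, plot-ready calibration and decision-curve CSVs, and a manifest
(config hash, seed, library versions) from which every number is
reproducible. Percentages are reported to one decimal, rounded half-up.
The analysis scripts run at n = 6,000 patients with 500 bootstrap
resamples (200 for the six sensitivity variants), sizes at which the full
study completes in a few minutes on one core while keeping binomial noise
on a 3–5 % event rate acceptable; the acceptance script's slope-recovery
check uses n = 100,000 to hold the Monte-Carlo tolerance at ±0.05.

## Known limitations

- The shipped model configurations are structural placeholders; no result
  computed from them says anything about the published models' actual
  coefficients.
- The calibration-slope treatment of Cox models (logistic refit of the
  binary 5-year outcome) is one defensible reading; survival-native
  alternatives (Poisson/pseudo-value approaches) are not implemented.
- MAPE uses absolute differences; a signed-difference reading of "average
  difference" would change Table-style outputs but not rankings.
- Whether the imputation model should include follow-up time as well as
  the outcome indicator is an open modelling choice; only the outcome
  indicator is included.
- No recalibration or model updating is performed — the pipeline measures
  transportability, it does not repair it.
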