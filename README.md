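# ckdval

External validation of published risk prediction models for the onset of
chronic kidney disease (CKD), built as a reusable, fully tested pipeline
over synthetic electronic-health-record (EHR) cohorts with known ground
truth.

Clinical prediction models for 5-year CKD onset — logistic regressions,
Cox proportional-hazards models with a published baseline survival, and
integer scoring systems — are routinely applied far from the populations
they were developed on. Whether they *transport* is an empirical question
with a standard answer sheet: discrimination (AUC, Harrell's c-index),
calibration (mean absolute prediction error, calibration slope,
calibration plots), decision-curve analysis, classification thresholds,
and case-mix diagnostics. This package implements that entire answer
sheet, plus the EHR phenotyping needed to produce the validation cohort in
the first place, for epidemiologists and methodologists who want to
exercise, test or extend an external-validation workflow without access to
confidential patient records.

## What is implemented

- **Synthetic EHR cohorts** (`ckdval.synthetic`): demographics, dated
  diagnostic codes, repeat prescriptions, longitudinal creatinine/eGFR
  series, death and move-out dates, configurable covariate prevalences and
  missingness — with a latent logistic risk model whose linear predictor
  and 5-year risk are stored per patient. Outcomes arise mechanistically:
  high-risk patients' eGFR trajectories drift below 60 mL/min/1.73 m².
- **Phenotyping** (`ckdval.phenotyping`): MDRD and CKD-EPI (2009) eGFR;
  CKD onset as *two consecutive eGFR values < 60 spanning ≥ 3 months, or a
  CKD stage 3–5 diagnostic code* (plus a relaxed single-measurement rule);
  entry/exclusion/censoring rules; predictor extraction with the 6-month
  repeat-prescription and 12-month laboratory lookback windows.
- **Multiple imputation** (`ckdval.imputation`): chained equations with
  predictive mean matching (continuous) and logistic draws (binary),
  10 imputations × 10 cycles by default.
- **Model registry** (`ckdval.models`): published models as declarative
  YAML (terms, transforms incl. fractional polynomials, coefficients,
  intercept or baseline survival); intercept reconstruction from
  development summaries, `β₀ = logit(π) − Σ βx̄`; Cox risk
  `1 − S₀(h)^exp(LP − LP̄)`; integer scores; mean-linear-predictor
  case-mix comparison.
- **Validation metrics** (`ckdval.metrics`): AUC, Harrell's c, MAPE,
  calibration slope and bins, Youden thresholds with PPV/sensitivity/
  specificity, net benefit `TP/n − (FP/n)·p_t/(1−p_t)` over a threshold
  grid, top-decile case capture, percentile bootstrap CIs (500 resamples).
- **Pipeline + CLI** (`ckdval.pipeline`, `ckdval` command): the study
  end-to-end with all six sensitivity variants (risk-factor subgroup,
  single-eGFR outcome, death-as-event, CKD-EPI, 4-year horizon,
  complete-case).

The shipped model configurations under `src/ckdval/model_configs/` carry
**synthetic placeholder coefficients** — the term structures mirror seven
published CKD models and five scoring systems, but the numbers are not the
published ones. Substitute published coefficients in the YAML files to
validate real models.

## Worked example

```python
from ckdval.synthetic import CohortParams, generate_cohort
from ckdval.phenotyping import OutcomeDefinition, build_cohort
from ckdval.pipeline import summarize_selection

bundle = generate_cohort(CohortParams(n_patients=6000, seed=2009))
cohort = build_cohort(bundle, OutcomeDefinition())
print(summarize_selection(bundle, OutcomeDefinition(), cohort=cohort))
```

prints

```
{'screened_adults': 6000, 'excluded_prevalent': 0, 'included': 6000,
 'complete_followup': 5437, 'complete_followup_pct': 90.6,
 'died_before_ckd': 184, 'died_before_ckd_pct': 3.1,
 'events': 298, 'events_pct': 5.0}
```

i.e. of 6,000 simulated adults with an in-window record, none were
excluded as prevalent CKD, 90.6 % either developed CKD or completed the
5-year horizon (the cohort on which fixed-horizon logistic models are
validated), 3.1 % died before developing CKD, and 298 incident CKD cases
accrued. The numbered scripts under `analysis/` continue from here:
`01_simulate_cohort.py` (generator targets vs realized), `02_phenotype_cohort.py`
(cohort flow and characteristics), `03_validate_models.py` (the main
validation tables under `results/main/`), `04_sensitivity_analyses.py`
(all six variants). A full run is also available as
`ckdval run --config <run.yaml>`.

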