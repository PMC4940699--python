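# SYNTHETIC placeholder coefficients: the term structure mirrors the
# published model (logistic, 2-year horizon, demographic + comorbidity
# predictors, proteinuria unavailable in the validation data and dropped),
# but the numbers are NOT the published ones. Substitute the published
# coefficients to reproduce a real validation.
name: bang-2007
family: logistic
horizon_years: 2
intercept: -5.0
threshold: null
terms:
  - {predictor: age, transform: identity, beta: 0.045}
  - {predictor: female, transform: identity, beta: 0.10}
  - {predictor: anaemia, transform: identity, beta: 0.80}
  - {predictor: proteinuria, transform: identity, beta: 0.90, dropped: true}
  - {predictor: hypertension, transform: identity, beta: 0.50}
  - {predictor: diabetes_any, transform: identity, beta: 0.70}
  - {predictor: cardiovascular, transform: identity, beta: 0.40}
  - {predictor: heart_failure, transform: identity, beta: 0.60}
  - {predictor: pvd, transform: identity, beta: 0.70}
development_summary:
  prevalence: 0.07046
  n: 8530
  summaries:
    age: 45.0
    female: 0.50
    anaemia: 0.08
    hypertension: 0.30
    diabetes_any: 0.08
    cardiovascular: 0.07
    heart_failure: 0.02
    pvd: 0.03
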