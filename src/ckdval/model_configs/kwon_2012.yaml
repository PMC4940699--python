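# SYNTHETIC placeholder coefficients (structure only). Logistic model,
# 1-year horizon; no published intercept (estimated from the development
# summary); proteinuria unavailable in the validation data and dropped.
name: kwon-2012
family: logistic
horizon_years: 1
intercept: null
threshold: null
terms:
  - {predictor: age, transform: identity, beta: 0.05}
  - {predictor: female, transform: identity, beta: 0.20}
  - {predictor: anaemia, transform: identity, beta: 1.00}
  - {predictor: proteinuria, transform: identity, beta: 1.20, dropped: true}
  - {predictor: hypertension, transform: identity, beta: 0.70}
  - {predictor: diabetes_t2, transform: identity, beta: 0.80}
  - {predictor: cardiovascular, transform: identity, beta: 0.50}
development_summary:
  prevalence: 0.015233
  n: 6565
  summaries:
    age: 45.0
    female: 0.50
    anaemia: 0.07
    hypertension: 0.20
    diabetes_t2: 0.07
    cardiovascular: 0.04
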