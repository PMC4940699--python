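# SYNTHETIC placeholder coefficients (structure only). Logistic model,
# 1-year horizon; intercept estimated from the development summary.
name: thakkinstian-2011
family: logistic
horizon_years: 1
intercept: null
threshold: null
terms:
  - {predictor: age, transform: identity, beta: 0.055}
  - {predictor: hypertension, transform: identity, beta: 0.90}
  - {predictor: diabetes_any, transform: identity, beta: 1.00}
  - {predictor: kidney_stones, transform: identity, beta: 0.60}
development_summary:
  prevalence: 0.175195
  n: 3459
  summaries:
    age: 50.0
    hypertension: 0.30
    diabetes_any: 0.12
    kidney_stones: 0.05
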