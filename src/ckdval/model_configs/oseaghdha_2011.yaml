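# SYNTHETIC placeholder coefficients (structure only). Compact logistic
# model (age, hypertension, diabetes), 10-year horizon, published intercept.
name: oseaghdha-2011
family: logistic
horizon_years: 10
intercept: -6.4
threshold: null
terms:
  - {predictor: age, transform: identity, beta: 0.065}
  - {predictor: hypertension, transform: identity, beta: 0.80}
  - {predictor: diabetes_any, transform: identity, beta: 0.90}
development_summary:
  prevalence: 0.091968
  n: 2490
  summaries:
    age: 58.0
    hypertension: 0.40
    diabetes_any: 0.08
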