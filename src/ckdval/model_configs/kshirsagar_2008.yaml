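# SYNTHETIC placeholder coefficients (structure only). Logistic model,
# 9-year horizon; the publication reports no intercept, so it is estimated
# at load time from the development summary (prevalence + predictor means).
name: kshirsagar-2008
family: logistic
horizon_years: 9
intercept: null
threshold: null
terms:
  - {predictor: age, transform: identity, beta: 0.06}
  - {predictor: female, transform: identity, beta: 0.15}
  - {predictor: anaemia, transform: identity, beta: 0.90}
  - {predictor: hypertension, transform: identity, beta: 0.60}
  - {predictor: diabetes_t2, transform: identity, beta: 0.70}
  - {predictor: cardiovascular, transform: identity, beta: 0.50}
  - {predictor: heart_failure, transform: identity, beta: 0.60}
  - {predictor: pvd, transform: identity, beta: 0.50}
development_summary:
  prevalence: 0.16948
  n: 9470
  summaries:
    age: 54.0
    female: 0.55
    anaemia: 0.10
    hypertension: 0.35
    diabetes_t2: 0.10
    cardiovascular: 0.08
    heart_failure: 0.03
    pvd: 0.04
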