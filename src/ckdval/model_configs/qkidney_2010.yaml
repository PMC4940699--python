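# SYNTHETIC placeholder coefficients (structure only). UK-developed Cox
# model at a native 5-year horizon; fractional-polynomial and log terms
# exercise the generic transform vocabulary (the original's exact
# fractional-polynomial constants are not transcribed).
name: qkidney-2010
family: cox
horizon_years: 5
baseline_survival: 0.985
lp_bar: 2.5
threshold: null
terms:
  - {predictor: age, transform: fp, power: 2, scale: 10.0, beta: 0.008, name: age_sq}
  - {predictor: bmi, transform: log, beta: 0.30, name: log_bmi}
  - {predictor: sbp, transform: identity, beta: 0.008}
  - {predictor: female, transform: identity, beta: 0.15}
  - {predictor: smoking, transform: ge, threshold: 2, beta: 0.20, name: current_smoker}
  - {predictor: deprivation, transform: identity, beta: 0.03}
  - {predictor: diabetes_any, transform: identity, beta: 0.60}
  - {predictor: rheumatoid_arthritis, transform: identity, beta: 0.20}
  - {predictor: cardiovascular, transform: identity, beta: 0.30}
  - {predictor: antihypertensive, transform: identity, beta: 0.50}
  - {predictor: heart_failure, transform: identity, beta: 0.30}
  - {predictor: pvd, transform: identity, beta: 0.25}
  - {predictor: nsaid, transform: identity, beta: 0.20}
  - {predictor: fh_kidney, transform: identity, beta: 0.80}
development_summary:
  prevalence: 0.014942
  n: 1591884
  summaries:
    age_sq: 24.0
    log_bmi: 3.26
    sbp: 128.0
    female: 0.50
    current_smoker: 0.25
    deprivation: 1.6
    diabetes_any: 0.05
    rheumatoid_arthritis: 0.01
    cardiovascular: 0.07
    antihypertensive: 0.14
    heart_failure: 0.01
    pvd: 0.015
    nsaid: 0.03
    fh_kidney: 0.0002
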