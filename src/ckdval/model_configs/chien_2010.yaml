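# SYNTHETIC placeholder coefficients (structure only; not the published
# values). Cox model, 4-year horizon, with a baseline survival at the
# horizon and a development-mean centering constant.
name: chien-2010
family: cox
horizon_years: 4
baseline_survival: 0.97
lp_bar: 0.2
threshold: null
terms:
  - {predictor: age, transform: centered, center: 50.0, beta: 0.06}
  - {predictor: bmi, transform: centered, center: 24.0, beta: 0.05}
  - {predictor: dbp, transform: centered, center: 75.0, beta: 0.02}
  - {predictor: diabetes_t2, transform: identity, beta: 0.90}
  - {predictor: stroke, transform: identity, beta: 0.50}
development_summary:
  prevalence: 0.03677
  n: 5168
  summaries:
    age: 1.2
    bmi: 0.2
    dbp: 1.0
    diabetes_t2: 0.09
    stroke: 0.03
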