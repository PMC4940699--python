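# SYNTHETIC placeholder points (structure only). Integer scoring system
# accompanying the bang-2007 model; proposed decision threshold 4.
name: bang-2007-score
family: score
horizon_years: 2
threshold: 4
terms:
  - {predictor: age, transform: ge, threshold: 50, points: 2, name: age_ge50}
  - {predictor: age, transform: ge, threshold: 70, points: 1, name: age_ge70}
  - {predictor: female, transform: identity, points: 1}
  - {predictor: anaemia, transform: identity, points: 1}
  - {predictor: proteinuria, transform: identity, points: 1, dropped: true}
  - {predictor: hypertension, transform: identity, points: 1}
  - {predictor: diabetes_any, transform: identity, points: 1}
  - {predictor: cardiovascular, transform: identity, points: 1}
  - {predictor: heart_failure, transform: identity, points: 1}
  - {predictor: pvd, transform: identity, points: 1}
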