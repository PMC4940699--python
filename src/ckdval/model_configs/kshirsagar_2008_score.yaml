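# SYNTHETIC placeholder points (structure only). Integer scoring system
# accompanying the kshirsagar-2008 model; proposed decision threshold 3.
name: kshirsagar-2008-score
family: score
horizon_years: 9
threshold: 3
terms:
  - {predictor: age, transform: ge, threshold: 60, points: 2, name: age_ge60}
  - {predictor: female, transform: identity, points: 1}
  - {predictor: anaemia, transform: identity, points: 2}
  - {predictor: hypertension, transform: identity, points: 1}
  - {predictor: diabetes_t2, transform: identity, points: 1}
  - {predictor: cardiovascular, transform: identity, points: 1}
  - {predictor: heart_failure, transform: identity, points: 1}
  - {predictor: pvd, transform: identity, points: 1}
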