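# SYNTHETIC placeholder points (structure only). Integer scoring system
# accompanying the kwon-2012 model; proposed decision threshold 4.
name: kwon-2012-score
family: score
horizon_years: 1
threshold: 4
terms:
  - {predictor: age, transform: ge, threshold: 50, points: 2, name: age_ge50}
  - {predictor: age, transform: ge, threshold: 65, points: 1, name: age_ge65}
  - {predictor: female, transform: identity, points: 1}
  - {predictor: anaemia, transform: identity, points: 2}
  - {predictor: proteinuria, transform: identity, points: 2, dropped: true}
  - {predictor: hypertension, transform: identity, points: 1}
  - {predictor: diabetes_t2, transform: identity, points: 1}
  - {predictor: cardiovascular, transform: identity, points: 1}
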