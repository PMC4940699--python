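# SYNTHETIC placeholder points (structure only). Integer scoring system
# accompanying the thakkinstian-2011 model; proposed decision threshold 5.
name: thakkinstian-2011-score
family: score
horizon_years: 1
threshold: 5
terms:
  - {predictor: age, transform: ge, threshold: 50, points: 2, name: age_ge50}
  - {predictor: age, transform: ge, threshold: 60, points: 1, name: age_ge60}
  - {predictor: hypertension, transform: identity, points: 2}
  - {predictor: diabetes_any, transform: identity, points: 2}
  - {predictor: kidney_stones, transform: identity, points: 1}
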