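# SYNTHETIC placeholder points (structure only). Integer scoring system
# accompanying the chien-2010 model; proposed decision threshold 7.
name: chien-2010-score
family: score
horizon_years: 4
threshold: 7
terms:
  - {predictor: age, transform: ge, threshold: 50, points: 3, name: age_ge50}
  - {predictor: age, transform: ge, threshold: 60, points: 2, name: age_ge60}
  - {predictor: bmi, transform: ge, threshold: 27, points: 1, name: bmi_ge27}
  - {predictor: dbp, transform: ge, threshold: 90, points: 1, name: dbp_ge90}
  - {predictor: diabetes_t2, transform: identity, points: 2}
  - {predictor: stroke, transform: identity, points: 1}
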