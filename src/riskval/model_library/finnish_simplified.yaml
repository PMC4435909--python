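# Simplified Finnish Diabetes Risk Score (Bergmann et al. 2007).
# Integer point score mapped to a probability through a logistic score
# link; predictor set (age, sex, BMI, antihypertensive medication, family
# history, smoking, corticosteroids) follows the validation study's
# summary of the model.
# SYNTHETIC RECONSTRUCTION: point values and the score link are editable
# placeholders, not a transcription; the link is set so the score yields
# the small absolute probabilities (strong underestimation in a
# high-prevalence population) characteristic of this model.
name: finnish_simplified
source_ref: "Bergmann A et al. Horm Metab Res 2007 (reconstructed points)"
link: logistic_score
score_link:
  intercept: -4.3
  slope: 0.22
provenance: >-
  Synthetic stand-in point values and score link; predictor structure
  matches the validation study's model summary.
terms:
  - variable: age
    transform: binned
    cuts: [45.0, 55.0]
    values: [0.0, 2.0, 3.0]
  - variable: sex
    transform: indicator
    category: male
    coefficient: 1.0
  - variable: bmi
    transform: binned
    cuts: [25.0, 30.0]
    values: [0.0, 1.0, 3.0]
  - variable: on_htn_meds
    transform: indicator
    category: true
    coefficient: 2.0
  - variable: fh_any
    transform: indicator
    category: true
    coefficient: 3.0
  - variable: smoker
    transform: indicator
    category: true
    coefficient: 1.0
  - variable: corticosteroids
    transform: indicator
    category: true
    coefficient: 1.0
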