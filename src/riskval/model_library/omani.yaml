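# Omani Diabetes Risk Score (Al-Lawati & Tuomilehto 2007).
# Integer point score over age, BMI, waist circumference, family history
# and measured blood pressure, mapped to a probability through a logistic
# score link.
# SYNTHETIC RECONSTRUCTION: point values and the score link below are
# editable placeholders matching the published predictor set, not a
# transcription of the published table.  Replace before substantive use.
name: omani
source_ref: "Al-Lawati JA, Tuomilehto J. Diabetes Res Clin Pract 2007 (reconstructed points)"
link: logistic_score
score_link:
  intercept: -3.4
  slope: 0.30
provenance: >-
  Synthetic stand-in point values and score link; predictor structure
  matches the published model.
terms:
  - variable: age
    transform: binned
    cuts: [35.0, 45.0, 55.0]
    values: [0.0, 1.0, 2.0, 3.0]
  - variable: bmi
    transform: binned
    cuts: [25.0, 30.0]
    values: [0.0, 1.0, 2.0]
  - variable: waist
    transform: binned
    cuts: [90.0, 100.0]
    values: [0.0, 2.0, 3.0]
  - variable: fh_any
    transform: indicator
    category: true
    coefficient: 2.0
  - variable: elevated_bp
    transform: indicator
    category: true
    coefficient: 2.0
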