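# Rotterdam Predictive Model 1 (Baan et al. 1999).
# Logistic model on age, sex, BMI and antihypertensive medication.
# SYNTHETIC RECONSTRUCTION: the published equation was not available for
# transcription; the coefficients below are editable placeholders matching
# the published predictor set, with an intercept giving the marked risk
# underestimation this model shows in high-prevalence settings.
name: rotterdam_1
source_ref: "Baan CA et al. Diabetes Care 1999;22:213-9 (reconstructed coefficients)"
link: logistic
intercept: -8.8
provenance: >-
  Synthetic stand-in coefficients; predictor structure matches the
  published model, numeric values are reconstructed, not transcribed.
terms:
  - variable: age
    transform: identity
    coefficient: 0.065
  - variable: sex
    transform: indicator
    category: male
    coefficient: 0.45
  - variable: bmi
    transform: identity
    coefficient: 0.10
  - variable: on_htn_meds
    transform: indicator
    category: true
    coefficient: 0.55
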