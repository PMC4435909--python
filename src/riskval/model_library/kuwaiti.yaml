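# Kuwaiti Risk Score (Al Khalaf et al. 2008).
# SYNTHETIC RECONSTRUCTION: the published equation was not available for
# transcription; the predictor set (age, antihypertensive medication,
# family history, waist circumference) follows the published description,
# and the coefficients below are editable placeholders chosen to give a
# realistic risk gradient with mild underestimation in a high-prevalence
# population.  Replace with the published values before substantive use.
name: kuwaiti
source_ref: "Al Khalaf MM et al. East Mediterr Health J 2008 (reconstructed coefficients)"
link: logistic
intercept: -3.9
provenance: >-
  Synthetic stand-in coefficients; predictor structure matches the
  published model, numeric values are reconstructed, not transcribed.
terms:
  - variable: age
    transform: binned
    cuts: [35.0, 45.0, 55.0]
    values: [0.0, 0.55, 1.05, 1.45]
  - variable: on_htn_meds
    transform: indicator
    category: true
    coefficient: 0.62
  - variable: fh_any
    transform: indicator
    category: true
    coefficient: 0.86
  - variable: waist
    transform: binned
    cuts: [90.0, 100.0]
    values: [0.0, 0.5, 0.95]
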