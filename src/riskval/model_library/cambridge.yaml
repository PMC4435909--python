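# Cambridge Diabetes Risk Score (Griffin et al. 2000).
# Logistic regression equation as reprinted in the original publication.
# The cohort questionnaire records current smoking only, so the score's
# ex-smoker term (-0.218) is inapplicable and smoking enters as a single
# current-smoker indicator.
name: cambridge
source_ref: "Griffin SJ et al. Diabetes Metab Res Rev 2000;16:164-71"
link: logistic
intercept: -6.322
provenance: >-
  Coefficients transcribed from the original publication's logistic
  equation; the ex-smoker term is dropped because the cohort records
  current smoking status only.
terms:
  - variable: age
    transform: identity
    coefficient: 0.063
  - variable: sex
    transform: indicator
    category: male
    coefficient: 0.879
  - variable: bmi
    transform: binned
    cuts: [25.0, 27.5, 30.0]
    values: [0.0, 0.699, 1.97, 2.518]
  - variable: on_htn_meds
    transform: indicator
    category: true
    coefficient: 1.222
  - variable: corticosteroids
    transform: indicator
    category: true
    coefficient: 2.191
  - variable: fh_category
    transform: indicator
    category: parent_or_sibling
    coefficient: 0.728
  - variable: fh_category
    transform: indicator
    category: parent_and_sibling
    coefficient: 0.753
  - variable: smoker
    transform: indicator
    category: true
    coefficient: 0.855
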