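"""Score the five bundled risk models and print their performance block.

For each model: E/O ratio (calibration-in-the-large; >1 overestimates,
<1 underestimates), Brier score (mean squared error, 0 = perfect), Yates
slope (risk separation between cases and non-cases), C statistic
(discrimination, 0.5 = chance) and the Youden-optimal threshold with its
sensitivity/specificity.
"""

from riskval import (
    apply_eligibility,
    c_statistic,
    brier_score,
    eo_ratio,
    generate_cohort,
    load_all_bundled_models,
    optimal_threshold,
    score_cohort,
    yates_slope,
)
from riskval.simulate import default_config

roster = generate_cohort(default_config(), seed=1)
models = load_all_bundled_models()

union = []
for m in models:
    union += [v for v in m.required_base_variables if v not in union]
analysis, _ = apply_eligibility(roster, union)
y = analysis["y"].to_numpy()
print(f"common analysis set: n = {len(analysis)}, events = {int(y.sum())}\n")

hdr = f"{'model':20s} {'E/O':>12s} {'Brier':>6s} {'Yates':>6s} {'C (95% CI)':>18s} {'thr':>5s} {'sens':>5s} {'spec':>5s}"
print(hdr)
for model in models:
    p = score_cohort(model, analysis)
    eo = eo_ratio(p, y)
    c = c_statistic(p, y)
    t = optimal_threshold(p, y)
    print(f"{model.name:20s} {eo.ratio:5.2f} ({eo.ci_low:.2f}-{eo.ci_high:.2f})"
          f" {brier_score(p, y):6.3f} {yates_slope(p, y):6.3f}"
          f" {c.c:.2f} ({c.ci_low:.2f}-{c.ci_high:.2f}) {t.threshold:5.2f}"
          f" {t.sensitivity:5.0f} {t.specificity:5.0f}")
# Models with E/O far from 1 are miscalibrated for this population even
# when their C statistic (ranking ability) is acceptable.
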