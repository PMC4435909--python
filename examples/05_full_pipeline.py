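"""Run the whole validation pipeline and render the report tables.

Equivalent to the CLI:
    riskval simulate --seed 1 --out cohort.csv
    riskval validate --cohort cohort.csv --models <dir> --seed 1 --out run.json
    riskval report run.json --format md
"""

from riskval import (
    generate_cohort,
    load_all_bundled_models,
    render_performance_table,
    render_subgroup_table,
    run_validation,
)
from riskval.simulate import default_config

roster = generate_cohort(default_config(), seed=1)
run = run_validation(roster, load_all_bundled_models(), seed=1, imputation_m=5)

print("overall performance (original vs intercept-adjusted):\n")
print(render_performance_table(run).to_string())
print("\nsubgroup performance (sex / age band / BMI band):\n")
print(render_subgroup_table(run).head(8).to_string())
print("\nimputation sensitivity (pooled C per model):")
for name, block in run["imputation_sensitivity"]["per_model"].items():
    print(f"  {name:20s} {block['pooled_c']:.3f} (range {block['min']:.3f}-{block['max']:.3f})")
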