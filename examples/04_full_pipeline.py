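"""End-to-end analysis report: QC -> summarise -> filter -> test.

Reproduces the full comparison on a simulated frontal-vs-broad cohort:
per-group counts through each stage, mean vector strength, mean absolute
heading with a bootstrap CI of the circular mean, and pairwise fly-level
permutation p-values for both statistics.
"""
from sunflight import (
    SimConfig,
    broad_group_spec,
    frontal_group_spec,
    generate_cohort,
    run_navigation_analysis,
)

config = SimConfig(duration_s=60.0)
specs = [
    broad_group_spec(label="control", n_flies=15),
    frontal_group_spec(label="experimental", n_flies=15),
]
cohort = generate_cohort(specs, config, seed=11)
report = run_navigation_analysis(
    cohort, seed=5, trial_duration_s=60.0, n_perm=10_000, n_boot=10_000
)
print(report.to_text())
print("The experimental group's frontally biased goals give a small mean")
print("absolute heading; matched controller noise keeps vector strength —")
print("the degree of stimulus stabilization — equivalent across groups.")
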