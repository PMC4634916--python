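"""A desk-scale replay of the carryover scenarios.

Scenario 7: each previous intervention allocation shifts later outcomes by
0.6 and each previous control allocation by 0.2.  Ignoring carryover biases
the patient-adjusted estimator (the within-patient comparisons absorb the
carryover into the treatment contrast); adjusting for both prior-allocation
counts restores the true effect of 0.4 and still beats parallel-group power.

300 replications keep this illustrative run under a minute; the shipped
study configuration uses 5000.
"""

from rerand import ExperimentConfig, run_experiment

config = ExperimentConfig(
    kind="scenario",
    scenario="s7_differential_carryover",
    replications=300,
    master_seed=2015,
    effect_mode="powered",
)
summary = run_experiment(config)
cols = ["analysis", "mean_estimate", "rejection_rate", "power_diff_vs_parallel"]
print(summary.table[cols].round(3).to_string(index=False))
print("""
Reading: 'adjusted' (no carryover adjustment) under-estimates the effect
(~0.27 vs 0.4); 'adjusted+A' over-corrects (~0.49); 'adjusted+A+B' is
unbiased and gains ~10pp power over the 80% parallel-group benchmark.
""")
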