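# All seven re-enrolment/carryover scenarios with their full analysis menus,
# under both the null and the 80%-powered treatment effect.
kind: table3
replications: 5000
master_seed: 20151105
effect_mode: both
parallel_benchmark: nominal_80
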