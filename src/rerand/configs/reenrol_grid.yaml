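# Five enrolment-count designs (100x1+50x2 ... 25x8) at ICC 0.50,
# with a paired simulated parallel-group comparator.
kind: reenrol_grid
icc: 0.5
replications: 5000
master_seed: 20151105
effect_mode: both
parallel_benchmark: simulated_parallel
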