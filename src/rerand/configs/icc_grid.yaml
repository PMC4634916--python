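# Base design (100 patients x1, 50 patients x2) across ICC 0.10-0.90,
# with a paired simulated parallel-group comparator of 200 patients.
kind: icc_grid
replications: 5000
master_seed: 20151105
effect_mode: both
parallel_benchmark: simulated_parallel
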