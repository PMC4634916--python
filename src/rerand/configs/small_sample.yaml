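# Small-sample type-I-error study: 5-30 patients x {2,4,8} periods,
# simple vs period-stratified permuted-block randomisation, ICC 0.75, null effect.
kind: small_sample
replications: 5000
master_seed: 20151105
effect_mode: "null"
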