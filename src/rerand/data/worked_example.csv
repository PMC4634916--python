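patient_id,period,allocation,prior_intervention,prior_control,total_enrolments,outcome,time
1,1,1,0,0,1,,
2,1,0,0,0,1,,
3,1,0,0,0,2,,
3,2,0,0,1,2,,
4,1,1,0,0,2,,
4,2,0,1,0,2,,
5,1,1,0,0,4,,
5,2,0,1,0,4,,
5,3,1,1,1,4,,
5,4,1,2,1,4,,
6,1,0,0,0,6,,
6,2,0,0,1,6,,
6,3,0,0,2,6,,
6,4,1,0,3,6,,
6,5,1,1,3,6,,
6,6,0,2,3,6,,
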