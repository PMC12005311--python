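cohort,n,n_deferred,n_positive_impact,printed_adoption_pct
internal,192,36,23,81.3
external1,99,26,19,73.7
external2,50,4,3,92.0
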