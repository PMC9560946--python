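field	value
verdict	heterokaryon-consistent
partition	A,B,A,A,B,A
partition_score	1
permutation_p	0.005
density_used	0.875
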