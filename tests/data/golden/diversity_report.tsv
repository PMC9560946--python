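statistic	value
Total number of SNPs	87
Number of SNPs non-rep	70
Number of SNPs coding region	8
Density SNP/kb	0.88
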