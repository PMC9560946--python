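statistic	value
n_sites_input	1001
n_failed_hard_filters	51
n_cells_masked	0
n_sites_removed_missingness	2
n_snp_sites	87
n_all_alt_sites	0
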