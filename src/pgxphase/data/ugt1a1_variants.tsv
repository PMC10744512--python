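# UGT1A1 distal-promoter SNVs, 1-based coordinates in the synthetic locus window.
# The TA promoter repeat itself is described in gene_models.yaml, not here.
# gene	var_id	coord	ref	alt
UGT1A1	rs4124874	1200	T	G
UGT1A1	rs10929302	1700	G	A
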