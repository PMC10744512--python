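# UGT1A1 star alleles. TA-repeat alleles are discriminated by repeat count
# (5/6/7/8 -> *36/*1/*28/*37); *60 and *93 are distal promoter SNV markers.
# *93 tags *28 linkage only and carries no independent function.
# gene	name	defining_variants	core_variant	ta_repeats	activity_value	function_class	acetylation_class	flags
UGT1A1	*1	-	-	6	1.0	normal	-	reference
UGT1A1	*28	-	-	7	0.3	decreased	-	-
UGT1A1	*36	-	-	5	1.0	normal	-	-
UGT1A1	*37	-	-	8	0.3	decreased	-	-
UGT1A1	*60	rs4124874	rs4124874	-	0.7	decreased	-	-
UGT1A1	*93	rs10929302	rs10929302	-	unknown	unknown	-	marker
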