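# NAT2 star alleles: acetylator classes per the rapid (*4,*12,*13) / slow (*5,*6,*7,*14)
# haplotype lists; *11 is never classed by either list -> unclassified.
# gene	name	defining_variants	core_variant	ta_repeats	activity_value	function_class	acetylation_class	flags
NAT2	*4	-	-	-	unknown	normal	rapid	reference
NAT2	*5	c.341T>C	c.341T>C	-	unknown	decreased	slow	-
NAT2	*6	c.590G>A	c.590G>A	-	unknown	decreased	slow	-
NAT2	*7	c.857G>A	c.857G>A	-	unknown	decreased	slow	-
NAT2	*11	c.481C>T	c.481C>T	-	unknown	unknown	unclassified	-
NAT2	*12	c.803A>G	c.803A>G	-	unknown	normal	rapid	-
NAT2	*13	c.282C>T	c.282C>T	-	unknown	normal	rapid	-
NAT2	*14	c.191G>A	c.191G>A	-	unknown	decreased	slow	-
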