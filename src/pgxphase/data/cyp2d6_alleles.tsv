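# CYP2D6 star alleles. Activity values calibrated so that every
# additive-consistent printed activity score is reproduced exactly:
# *1=*2=*35=*34=1.0; *3=*4=*5=*6=0; *9=*10=*41=0.25; *17=*29=*43=0.5;
# hybrids 0. Non-additive diplotypes live in the override table
# (thresholds.yaml). *43 activity inferred from the *29/*43 -> 1.0 row.
# gene	name	defining_variants	core_variant	ta_repeats	activity_value	function_class	acetylation_class	flags
CYP2D6	*1	-	-	-	1.0	normal	-	reference
CYP2D6	*2	tag2	tag2	-	1.0	normal	-	-
CYP2D6	*3	tag3	tag3	-	0	none	-	-
CYP2D6	*4	tag4	tag4	-	0	none	-	-
CYP2D6	*5	-	-	-	0	none	-	deletion
CYP2D6	*6	tag6	tag6	-	0	none	-	-
CYP2D6	*9	tag9	tag9	-	0.25	decreased	-	-
CYP2D6	*10	tag10	tag10	-	0.25	decreased	-	-
CYP2D6	*17	tag17	tag17	-	0.5	decreased	-	-
CYP2D6	*28	tag28	tag28	-	unknown	unknown	-	-
CYP2D6	*29	tag29	tag29	-	0.5	decreased	-	-
CYP2D6	*33	tag33	tag33	-	1.0	normal	-	-
CYP2D6	*34	tag34	tag34	-	1.0	normal	-	-
CYP2D6	*35	tag35	tag35	-	1.0	normal	-	-
CYP2D6	*41	tag41	tag41	-	0.25	decreased	-	-
CYP2D6	*43	tag43	tag43	-	0.5	decreased	-	-
CYP2D6	*45	tag45	tag45	-	1.0	normal	-	-
CYP2D6	*53	tag53	tag53	-	1.0	normal	-	-
CYP2D6	*71	tag71	tag71	-	unknown	unknown	-	-
CYP2D6	*80	tag80	tag80	-	unknown	unknown	-	-
CYP2D6	*68	tag68	tag68	-	0	none	-	hybrid
CYP2D6	*36	tag36	tag36	-	0	none	-	hybrid
CYP2D6	*4N	tag4N	tag4N	-	0	none	-	hybrid
CYP2D6	*13	tag13	tag13	-	0	none	-	hybrid
CYP2D6	*61	tag61	tag61	-	0	none	-	hybrid
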