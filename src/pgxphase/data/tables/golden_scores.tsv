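# Printed (diplotype -> activity score, phenotype) rows for CYP2D6 and UGT1A1
# (golden reference for the scoring engine). Duplicate diplotypes across
# samples are listed once. The CYP2D6 copy-number triplet (2D6/2D7/hybrid) and
# reported structural form are kept verbatim where printed.
# gene	diplotype	activity_score	phenotype	cn_triplet	structural_form
CYP2D6	*4/*41,*68	0.5	PM	2/2/1	hybrid
CYP2D6	*2 x 2/*41	2.25	NM	3/2/0	duplication
CYP2D6	*1/*4 x 2	1.0	IM	3/2/0	duplication
CYP2D6	*5/*17	0.5	PM	1/2/0	deletion
CYP2D6	*2 x 2/*5	1.0	IM	3/2/0	deletion and duplication
CYP2D6	*1 x 2/*4,*68	2.0	NM	3/2/1	composite
CYP2D6	*1/*41	1.25	NM	2/2/0	snv/indel
CYP2D6	*29/*43	1.0	IM	2/2/0	snv/indel
CYP2D6	*1/*10	1.25	NM	2/2/0	snv/indel
CYP2D6	*4/*6	0	PM	2/2/0	snv/indel
CYP2D6	*9/*41	0.5	PM	2/2/0	snv/indel
CYP2D6	*2/*2	2.0	NM	2/2/0	snv/indel
UGT1A1	*36/*60	2.125	NM	-	-
UGT1A1	*1/*28	1.3	IM	-	-
UGT1A1	*1/*60	1.7	IM	-	-
UGT1A1	*1/*1	2.0	NM	-	-
UGT1A1	*28/*28	0.6	PM	-	-
UGT1A1	*36/*37	1.3	IM	-	-
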