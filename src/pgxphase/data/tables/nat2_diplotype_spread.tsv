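# Cohort spread of NAT2 clinical diplotypes (411 patients) with the reported
# ambiguity category: non-ambiguous = statistical phasing after short-read
# sequencing could assign each haplotype; ambiguous = it could not.
# category	diplotype	count
non-ambiguous	*5,*11,*12/*5,*11,*12	70
non-ambiguous	*4/*5,*11,*12	53
non-ambiguous	*6,*13/*6,*13	42
non-ambiguous	*4/*6,*13	33
non-ambiguous	*4/*4	20
non-ambiguous	*6/*13	14
non-ambiguous	*5/*11,*12	7
non-ambiguous	*4/*5,*12	5
non-ambiguous	*5,*11/*12	5
non-ambiguous	*4/*12	4
non-ambiguous	*7/*13	4
non-ambiguous	*5,*11,*12/*5,*12	3
non-ambiguous	*4/*7,*13	2
non-ambiguous	*5,*11/*5,*11,*12	2
non-ambiguous	*5,*12/*11	2
non-ambiguous	*5,*12/*11,*12	2
non-ambiguous	*6,*12/*13	2
non-ambiguous	*4/*14,*13	1
non-ambiguous	*4/*5,*11	1
non-ambiguous	*4/*6,*12,*13	1
non-ambiguous	*4/*6	1
non-ambiguous	*5,*11,*12/*11,*12	1
non-ambiguous	*5,*11,*12/*13	1
non-ambiguous	*5/*11,*12,*13	1
non-ambiguous	*5/*12	1
non-ambiguous	*6,*13/*13	1
non-ambiguous	*5,*12/*14	1
non-ambiguous	*5,*14,*11,*12/*13	1
non-ambiguous	*5/*14,*11,*12,*13	1
ambiguous	*5,*11,*12/*6,*13	68
ambiguous	*5,*11,*12,*13/*6	7
ambiguous	*5,*11/*6,*12,*13	7
ambiguous	*5,*11,*12/*7,*13	6
ambiguous	*5,*6,*11/*12,*13	6
ambiguous	*5,*11/*6,*13	6
ambiguous	*4/*5,*6,*11,*12,*13	4
ambiguous	*5,*12/*6,*13	4
ambiguous	*5,*6,*13/*11,*12	3
ambiguous	*5,*6,*11,*12/*13	3
ambiguous	*5,*13/*6,*11,*12	2
ambiguous	*4/*5,*14,*11,*12	1
ambiguous	*4/*6,*14,*13	1
ambiguous	*5,*11,*12,*13/*7	1
ambiguous	*5,*12,*13/*6	1
ambiguous	*5,*12,*13/*6,*11	1
ambiguous	*5,*14,*12/*11	1
ambiguous	*5,*6,*11/*13	1
ambiguous	*5,*6,*12/*11,*13	1
ambiguous	*5,*6,*12/*13	1
ambiguous	*5/*6	1
ambiguous	*5/*7,*11,*12,*13	1
ambiguous	*6,*13/*7,*13	1
ambiguous	*6/*14,*13	1
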