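# CYP2D6 tag SNVs, 1-based coordinates in the synthetic 6 kb gene-unit window.
# Each star allele is tagged by a single discriminating SNV in this model
# (full PharmVar definitions are out of scope); hybrid tags sit upstream of
# the 2D6/2D7 junction at 4500 so hybrid copies still carry them.
# gene	var_id	coord	ref	alt
CYP2D6	tag2	800	C	T
CYP2D6	tag45	900	A	G
CYP2D6	tag35	1000	A	G
CYP2D6	tag53	1100	G	A
CYP2D6	tag41	1200	G	A
CYP2D6	tag33	1300	C	T
CYP2D6	tag9	1400	A	G
CYP2D6	tag71	1500	G	T
CYP2D6	tag10	1600	C	T
CYP2D6	tag80	1700	T	C
CYP2D6	tag17	1800	C	T
CYP2D6	tag29	2000	G	A
CYP2D6	tag43	2200	A	C
CYP2D6	tag3	2400	A	G
CYP2D6	tag4	2600	G	A
CYP2D6	tag6	2800	T	C
CYP2D6	tag28	3000	G	T
CYP2D6	tag34	3200	C	G
CYP2D6	tag68	3400	C	A
CYP2D6	tag36	3600	G	C
CYP2D6	tag4N	3800	T	G
CYP2D6	tag13	4000	A	T
CYP2D6	tag61	4200	C	G
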