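# Cohort spread of CYP2D6 complex structural forms (198 of 773 screened
# patients). Diplotype strings stored verbatim as reported; entries without a
# "/" are reported single-allele arrangements.
# category	diplotype	count
hybrid	*1/*4,*68	16
hybrid	*2/*4,*68	14
hybrid	*4/*41,*68	7
hybrid	*4 x 2,*68	5
hybrid	*1/*4,*4N	3
hybrid	*4/*4,*68	3
hybrid	*3/*4,*68	1
hybrid	*1/*2,*68	2
hybrid	*9/*4,*68	2
hybrid	*4/*35,*68	2
hybrid	*1/*2,*13	2
hybrid	*41/*4,*68	1
hybrid	*2/*41,*68	1
hybrid	*4/*1,*61	1
hybrid	*4/*6,*4N	1
hybrid	*10/*10,*36	1
hybrid	*4 x 2,*36	1
hybrid	*2/*10,*36	1
hybrid	*17/*45,*68	1
duplication/multiplication	*1/*2 x 2	20
duplication/multiplication	*2 x 2/*41	6
duplication/multiplication	*2 x 2/*4	4
duplication/multiplication	*2/*2 x 2	4
duplication/multiplication	*1 x 3	3
duplication/multiplication	*1/*4 x 2	2
duplication/multiplication	*2 x 3	2
duplication/multiplication	*10 x 2/*1	1
duplication/multiplication	*1 x 2/*53	1
duplication/multiplication	*4/*28 x 2	1
duplication/multiplication	*2 x 2/*28	1
duplication/multiplication	*2 x 2/*10	1
duplication/multiplication	*41/*71 x 2	1
duplication/multiplication	*2 x 2/*35	1
duplication/multiplication	*4 x 2/*9	1
duplication/multiplication	*1/*2 x 3	1
duplication/multiplication	*1 x 2/*9	1
duplication/multiplication	*1 x 2/*29	1
duplication/multiplication	*1 x 2/*41	1
duplication/multiplication	*2 x 3/*29	1
duplication/multiplication	*35 x 3	1
duplication/multiplication	*4/*9 x 2	1
duplication/multiplication	*3 x 2/*41	1
duplication/multiplication	*2 x 2/*17	1
duplication/multiplication	*2 x 2/*33	1
deletion	*1/*5	25
deletion	*4/*5	7
deletion	*2/*5	6
deletion	*5/*41	4
deletion	*5/*35	2
deletion	*5/*17	2
deletion	*5/*9	2
deletion	*3/*5	2
deletion	*5/*10	2
deletion	*5/*34	1
deletion	*5/*29	1
deletion	*5/*28	1
composite	*2 x 2/*4,*68	5
composite	*1/*4,*68 x 2	2
composite	*4 x 2,*68 x 2	2
composite	*1 x 2/*4,*68	1
composite	*5/*4,*68	1
composite	*1/*4,*68 x 3	1
composite	*3/*4,*68	1
composite	*4/*28,*68 x 2	1
composite	*2 x 3/*68	1
composite	*2/*5,*36	1
composite	*2 x 2/*41,*80	1
composite	*10 x 2,*36 x 2	1
composite	*4 x 2,*4N x 2	1
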