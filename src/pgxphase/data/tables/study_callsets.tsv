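# The thirteen clinical samples called by both sequencing methods, transcribed
# from the per-gene comparison tables (CYP2D6 structural/CNV calls, UGT1A1 TA
# repeats, NAT2 phasing) plus the reported UGT1A1 *60/*93 promoter-marker
# depths. aux_markers: var_id:genotype:depth pairs, ";"-separated, "-" = none
# reported (hom-ref at adequate depth). Sample 4's CYP2D6 phenotype is stored
# as the single printed metabolizer status (IM) for both methods, matching the
# reported phenotype concordance.
# sample	method	gene	diplotype	phenotype	aux_markers
Sample 1	SRS	CYP2D6	*5/*17	PM	-
Sample 1	LRS	CYP2D6	*5/*17	PM	-
Sample 1	SRS	UGT1A1	*36/*60	NM	rs4124874:het:1900;rs10929302:hom-ref:1800
Sample 1	LRS	UGT1A1	*36/*60	NM	rs4124874:het:25;rs10929302:hom-ref:24
Sample 1	SRS	NAT2	*4/*5,*12	IA	-
Sample 1	LRS	NAT2	*4/*5,*12	IA	-
Sample 2	SRS	CYP2D6	*2/*2	NM	-
Sample 2	LRS	CYP2D6	*2/*2	NM	-
Sample 2	SRS	UGT1A1	*1/*28	IM	rs4124874:het:2157;rs10929302:het:1501
Sample 2	LRS	UGT1A1	*1/*28	IM	rs4124874:hom-ref:3;rs10929302:hom-ref:3
Sample 2	SRS	NAT2	*4/*4	RA	-
Sample 2	LRS	NAT2	*4/*4	RA	-
Sample 3	SRS	CYP2D6	*2 x 2/*41	NM	-
Sample 3	LRS	CYP2D6	*2 x 2/*41	NM	-
Sample 3	SRS	UGT1A1	*1/*60	IM	rs4124874:het:2100;rs10929302:hom-ref:1700
Sample 3	LRS	UGT1A1	*1/*60	IM	rs4124874:het:22;rs10929302:hom-ref:21
Sample 3	SRS	NAT2	*6/*13	IA	-
Sample 3	LRS	NAT2	*4/*6,*13	IA	-
Sample 4	SRS	CYP2D6	*2/*2	IM	-
Sample 4	LRS	CYP2D6	*2 x 2/*5	IM	-
Sample 4	SRS	UGT1A1	*1/*1	NM	-
Sample 4	LRS	UGT1A1	*1/*1	NM	-
Sample 4	SRS	NAT2	*5,*12,*13/*6,*11	IA	-
Sample 4	LRS	NAT2	*6,*13,*12/*5,*11	IA	-
Sample 5	SRS	CYP2D6	*9/*41	PM	-
Sample 5	LRS	CYP2D6	*9/*41	PM	-
Sample 5	SRS	UGT1A1	*1/*28	IM	rs4124874:het:1763;rs10929302:het:1271
Sample 5	LRS	UGT1A1	*1/*28	IM	rs4124874:hom-ref:13;rs10929302:hom-ref:13
Sample 5	SRS	NAT2	*5,*11,*12/*5,*11,*12	SA	-
Sample 5	LRS	NAT2	*5,*11,*12/*5,*11,*12	SA	-
Sample 6	SRS	CYP2D6	*1/*41	NM	-
Sample 6	LRS	CYP2D6	*1/*41	NM	-
Sample 6	SRS	UGT1A1	*1/*1	NM	-
Sample 6	LRS	UGT1A1	*1/*1	NM	-
Sample 6	SRS	NAT2	*4/*5,*11,*12	IA	-
Sample 6	LRS	NAT2	*4/*5,*11,*12	IA	-
Sample 7	SRS	CYP2D6	*4/*6	PM	-
Sample 7	LRS	CYP2D6	*4/*6	PM	-
Sample 7	SRS	UGT1A1	*28/*28	PM	rs4124874:het:2000;rs10929302:het:1600
Sample 7	LRS	UGT1A1	*28/*28	PM	rs4124874:het:20;rs10929302:het:19
Sample 7	SRS	NAT2	*4/*6,*13	IA	-
Sample 7	LRS	NAT2	*4/*6,*13	IA	-
Sample 8	SRS	CYP2D6	*1/*10	NM	-
Sample 8	LRS	CYP2D6	*1/*10	NM	-
Sample 8	SRS	UGT1A1	*1/*28	IM	rs4124874:het:2300;rs10929302:het:1800
Sample 8	LRS	UGT1A1	*1/*28	IM	rs4124874:het:18;rs10929302:het:17
Sample 8	SRS	NAT2	*5,*11,*12/*5,*12	SA	-
Sample 8	LRS	NAT2	*5,*11,*12/*5,*12	SA	-
Sample 9	SRS	CYP2D6	*29/*43	IM	-
Sample 9	LRS	CYP2D6	*29/*43	IM	-
Sample 9	SRS	UGT1A1	*36/*37	IM	-
Sample 9	LRS	UGT1A1	*36/*37	IM	-
Sample 9	SRS	NAT2	*5,*12/*11	SA	-
Sample 9	LRS	NAT2	*12/*5,*11	SA	-
Sample 10	SRS	CYP2D6	*4/*41,*68	PM	-
Sample 10	LRS	CYP2D6	*4/*41,*68	PM	-
Sample 10	SRS	UGT1A1	*1/*28	IM	rs4124874:het:2600;rs10929302:het:2100
Sample 10	LRS	UGT1A1	*1/*28	IM	rs4124874:het:26;rs10929302:het:25
Sample 10	SRS	NAT2	*4/*5,*11,*12	IA	-
Sample 10	LRS	NAT2	*12/*5,*11	IA	-
Sample 11	SRS	CYP2D6	*1/*4 x 2	IM	-
Sample 11	LRS	CYP2D6	*1/*4 x 2	IM	-
Sample 11	SRS	UGT1A1	*1/*28	IM	rs4124874:het:2400;rs10929302:het:1900
Sample 11	LRS	UGT1A1	*1/*28	IM	rs4124874:het:21;rs10929302:het:20
Sample 11	SRS	NAT2	*6/*13	IA	-
Sample 11	LRS	NAT2	*12/*6,*13,*12	IA	-
Sample 12	SRS	CYP2D6	*1/*41	NM	-
Sample 12	LRS	CYP2D6	*1/*41	NM	-
Sample 12	SRS	UGT1A1	*1/*28	IM	rs4124874:het:3492;rs10929302:het:2725
Sample 12	LRS	UGT1A1	*1/*28	IM	rs4124874:no-call:0;rs10929302:no-call:0
Sample 12	SRS	NAT2	*5,*11,*12/*5,*11,*12	SA	-
Sample 12	LRS	NAT2	*5,*11,*12/*5,*11,*12	SA	-
Sample 13	SRS	CYP2D6	*1 x 2/*4,*68	NM	-
Sample 13	LRS	CYP2D6	*1 x 2/*4,*68	NM	-
Sample 13	SRS	UGT1A1	*28/*28	PM	rs4124874:het:2200;rs10929302:het:1700
Sample 13	LRS	UGT1A1	*28/*28	PM	rs4124874:het:23;rs10929302:het:22
Sample 13	SRS	NAT2	*6,*13/*6,*13	SA	-
Sample 13	LRS	NAT2	*6,*13/*6,*13	SA	-
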