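# Novel nonsynonymous singleton EFR3A variants, cases (n=2196) and controls (n=3389), hg19 coordinates.
# Tri-state transmission columns (father/mother/sib): + carrier, - non-carrier, . unknown.
# ref "*" with alt "I:<seq>" denotes an insertion at the printed position.
cohort_group	subject_id	exon	protein_change	chrom	pos	ref	alt	sex	father	mother	sib	phylop	gerp	consurf	crystal_class	is_index_de_novo
SSC_case	12093.p1	3	R70C	8	132957112	C	T	M	+	-	.	2.95617	5.73	-1.51	deleterious	false
SSC_case	12610.p1	4	L118P	8	132958867	T	C	M	+	-	-	3.21686	5.47	-0.73	deleterious	false
SSC_case	11572.p1	7	G243A	8	132968104	G	C	M	-	+	+	6.387	5.64	-0.291	benign	false
SSC_case	11379.p1	10	F338S	8	132982744	T	C	F	-	-	-	4.58456	5.54	-1.107	deleterious	true
SSC_case	11473.p1	15	I534T	8	132996411	T	C	M	-	+	+	4.78917	6.02	-0.113	not_assessable	false
SSC_case	11577.p1	15	I576_A577insI	8	132996539	*	I:ATT	M	-	+	+	3.628	5.03	0.043	not_assessable	false
SSC_case	11808.p1	22	T785A	8	133015525	A	G	F	-	+	-	3.02491	4.27	-0.312	not_assessable	false
SSC_case	13507.p1	5	F123L	8	132962216	T	C	M	-	+	-	4.86423	5.51	-1.377	deleterious	false
SSC_case	11027.p1	7	G216Sfs*12	8	132968022	*	I:TCGCATA	M	-	+	-	6.995	6.07	-1.591	deleterious	false
AASC_case	20094	3	K50E	8	132957052	A	G	M	.	.	.	5.32367	5.55	-1.59	deleterious	false
AASC_case	00HI1409C	9	A321S	8	132980647	G	T	M	.	.	.	3.10583	5.51	-0.66	benign	false
AASC_case	00HI1533A	10	V337L	8	132982740	G	C	M	.	.	.	6.32607	5.54	-0.986	benign	false
AASC_case	06C57233	14	D504G	8	132991604	A	G	M	.	.	.	4.41785	5.06	-0.002	not_assessable	false
AASC_case	07C71126	14	L508P	8	132991616	T	C	M	.	.	.	4.19838	5.06	0.349	not_assessable	false
AASC_case	20072	14	I510V	8	132991621	A	G	M	.	.	.	2.07681	3.88	0.088	not_assessable	false
AASC_case	98HI0204A	15	Q528R	8	132996393	A	G	M	.	.	.	5.21937	6.02	0.08	not_assessable	false
AASC_case	08C73985A	17	M646V	8	132998507	A	G	M	.	.	.	2.13232	4.65	2.129	not_assessable	false
NINDS_control	ND11540	2	P14R	8	132952776	C	G	M	.	.	.	5.86267	5.93	-1.264	benign	false
NE_control	S19G8	5	R161*	8	132962330	C	T	M	.	.	.	6.995	6.07	-1.591	deleterious	false
NE_control	S16H7	6	M194V	8	132966156	A	G	F	.	.	.	5.34254	5.73	-0.985	benign	false
NE_control	S6G2	9	E320D	8	132980646	G	T	F	.	.	.	1.06245	2.3	-0.162	benign	false
NE_control	S6B11	10	N354D	8	132982791	A	G	M	.	.	.	0.272244	0.403	1.188	benign	false
NE_control	S4H5	13	T451M	8	132991119	C	T	M	.	.	.	2.72643	5.71	0.289	benign	false
NE_control	S1B3	15	R532W	8	132996404	C	T	F	.	.	.	0.659283	0.794	1.218	not_assessable	false
NE_control	S15E2	15	D570G	8	132996519	A	G	F	.	.	.	5.21937	6.02	-0.169	not_assessable	false
AASC_control	04C27095A	3	G55C	8	132957067	G	T	F	.	.	.	6.81431	5.73	-1.321	benign	false
AASC_control	05C42103	4	F100L	8	132958812	T	C	M	.	.	.	4.82034	5.47	-0.879	benign	false
AASC_control	05C42750	8	D268G	8	132971858	A	G	F	.	.	.	4.99605	5.64	0.396	benign	false
AASC_control	05C45515	15_16	.	8	132996549	T	C	F	.	.	.	6.995	6.07	-1.591	not_assessable	false
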