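chrom	gene	cpg_id	pos	n_snp_candidates	n_mqtls
1	AVPR1B	cg09069072	15482754	13	5
1	GFI1	cg09662411	92946132	10	2
1	GFI1	cg09935388	92947588	10	2
1	GFI1	cg10399789	92945668	9	6
1	GFI1	cg12876356	92946825	10	2
1	GFI1	cg18146737	92946701	10	2
1	GFI1	cg18316974	92947035	10	2
1	GNG12	cg25189904	68299493	5	2
1	NOS1AP	cg11231349	162050657	4	2
1	TMEM51	cg21913886	15485346	14	9
1	unassigned	cg03547355	227003061	8	2
1	unassigned	cg12547807	9473751	9	1
1	unassigned	cg21393163	12217630	8	2
1	unassigned	cg26764244	68299511	3	3
2	2q37.1	cg05951221	233284402	5	1
2	2q37.1	cg03329539	233283329	5	2
2	ALPP	cg23667432	233244439	5	2
2	NFE2L2	cg26271591	178125956	8	6
2	SNED1	cg26718213	241976081	9	4
2	unassigned	cg27241845	233250371	5	2
3	GPX1	cg18642234	49394623	10	5
5	AHRR	cg03604011	400201	15	5
5	AHRR	cg03991871	368448	9	1
5	AHRR	cg11902777	368843	9	4
5	AHRR	cg12806681	368395	9	2
5	AHRR	cg14817490	392920	15	4
5	AHRR	cg17287155	393347	15	1
5	AHRR	cg23576855	373300	9	7
5	AHRR	cg23916896	368805	9	4
6	6p21.33	cg06126421	30720081	16	8
6	CDKN1A	cg15474579	36645813	22	8
6	IER3	cg15342087	30720210	16	2
6	IER3	cg24859433	30720204	16	3
6	TIAM2	cg00931843	155442993	6	1
6	VARS	cg17619755	31760629	16	8
6	unassigned	cg14753356	30720109	8	2
7	C7orf40	cg03440944	45023330	5	1
7	CNTNAP2	cg11207515	146904206	14	7
7	CNTNAP2	cg25949550	145814306	11	8
7	GNA12	cg19717773	2847554	22	22
7	HOXA7	cg08396193	27193709	7	1
7	LRRN3	cg11556164	110738316	5	5
7	MYO1G	cg12803068	45002919	10	1
7	MYO1G	cg22132788	45002487	10	1
7	TNRC18	cg09022230	5457226	24	3
8	ZC3H3	cg26361535	144576604	8	1
8	unassigned	cg19589396	103937374	15	2
9	unassigned	cg01692968	108005349	2	2
10	ARID5B	cg25953130	63753550	6	3
11	KCNQ1	cg07123182	2722391	13	2
11	KCNQ1	cg26963277	2722408	13	3
11	KCNQ1	cg01744331	2722358	13	3
11	KCNQ1OT1	cg16556677	2722402	13	2
11	PRSS23	cg11660018	86510915	9	2
11	PRSS23	cg23771366	86510999	9	2
11	unassigned	cg16611234	58870075	10	10
14	C14orf43	cg01731783	74211789	6	1
14	C14orf43	cg10919522	74227441	5	1
15	ANPEP	cg23161492	90357203	19	6
15	SEMA7A	cg00310412	74724919	13	9
16	ITGAL	cg09099830	30485486	3	2
16	XYLT1	cg16794579	17562419	3	1
17	LOC100130933	cg07251887	73641810	6	2
17	STXBP4	cg07465627	53167407	8	4
19	CPAMD8	cg15159987	17003890	15	4
19	CRTC1	cg23973524	18873223	12	1
19	F2RL3	cg03636183	17000586	17	1
19	PPP1R15A	cg03707168	49379127	10	4
21	ETS2	cg23110422	40182073	6	3
22	NCF4	cg02532700	37257404	8	2
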