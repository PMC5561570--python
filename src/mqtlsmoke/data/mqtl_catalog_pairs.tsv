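cpg_id	chrom	cpg_pos	snp_id	snp_pos	minor_allele	distance	fdr	maf
cg03636183	19	17000586	rs2227357	17003553	A	2967	0.048	0.125
cg05951221	2	233284402	rs790051	233282536	A	-1866	0.00062	0.226
cg03329539	2	233283329	rs790051	233282536	A	-793	0.031	0.226
cg03329539	2	233283329	rs34547337	233300755	T	17426	1.5e-05	0.314
cg14817490	5	392920	rs75509302	365653	C	-27267	0.002	0.144
cg14817490	5	392920	rs11746079	410980	C	18060	0.0015	0.154
cg14817490	5	392920	rs72717419	431996	T	39076	0.021	0.207
cg14817490	5	392920	rs2672725	434981	G	42061	0.042	0.117
cg23576855	5	373300	rs75509302	365653	C	-7647	3.4e-100	0.144
cg11902777	5	368843	rs75509302	365653	C	-3190	1.4e-07	0.144
cg17287155	5	393347	rs75509302	365653	C	-27694	7.8e-05	0.144
cg03991871	5	368448	rs75509302	365653	C	-2795	0.0001	0.144
cg12806681	5	368395	rs75509302	365653	C	-2742	0.00012	0.144
cg23916896	5	368805	rs75509302	365653	C	-3152	0.00095	0.144
cg03604011	5	400201	rs75509302	365653	C	-34548	0.0011	0.144
cg10399789	1	92945668	rs34835481	92991624	T	45956	2.2e-05	0.21
cg12876356	1	92946825	rs34835481	92991624	T	44799	0.0013	0.21
cg09662411	1	92946132	rs34835481	92991624	T	45492	0.0019	0.21
cg18146737	1	92946701	rs34835481	92991624	T	44923	0.002	0.21
cg18316974	1	92947035	rs34835481	92991624	T	44589	0.003	0.21
cg09935388	1	92947588	rs34835481	92991624	T	44036	0.016	0.21
cg12876356	1	92946825	rs79050605	92925962	G	-20863	0.00037	0.202
cg18146737	1	92946701	rs79050605	92925962	G	-20739	0.0011	0.202
cg18316974	1	92947035	rs79050605	92925962	G	-21073	0.0017	0.202
cg09662411	1	92946132	rs79050605	92925962	G	-20170	0.0019	0.202
cg09935388	1	92947588	rs79050605	92925962	G	-21626	0.0022	0.202
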