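gwas_snp	p_value	phenotype	pmid	ld_r2	phastcons	proxy_rsid	maf	fst	gene	mir	alleles	svr_score	seed_type	coexpression_count	eqtl_tissues
rs10089	2.00E-06	Ileal carcinoids	21139019	1	0.6692	rs10089	0.35	0.08	SLC12A2	hsa-miR-421	C/T	-0.682	8mer	23	NA
rs6504340	6.00E-07	Primary tooth dev	20195514	0.9	0.6635	rs1042822	0.18	NA	HOXB2	hsa-miR-186	G/T	-1.341	8mer	62	NA
rs328	9.00E-23	HDL cholesterol	18193044	0.93	0.685	rs1059611	0.13	0.03	LPL	hsa-miR-136	T/C	-0.635	7mer-m8	36	NA
rs10503669	4.00E-19		18193043	0.93
rs12678919	2.00E-34		19060906	0.93
rs17482753	3.00E-11		20031538	0.93
rs325	8.00E-26		20864672
rs6590330	2.00E-25	Systemic lupus erythematosus	19838193	1	0.8332	rs1128334	0.06	0.44	ETS1	hsa-miR-381	C/T	-1.166	7mer-m8	33	F
rs1128334	2.00E-11		20169177
rs10941694	9.00E-06	Chronic kidney disease and serum creatinine concentration	20686651	1	0.7345	rs12522910	0.14	NA	HCN1	hsa-miR-653	T/C	-1.352	8mer	9	NA
rs326	5.00E-12	Triglycerides	18193046	0.96	0.6217	rs13702	0.14	0.42	LPL	hsa-miR-410	T/C	-1.159	8mer	19	NA
rs2083637	2.00E-10	Metabolic Syndrome	20694148	0.92
rs10105606	4.00E-26	Hypertriglycerdemia	20864672	0.82
rs1008953	1.00E-07	Psoriasis	20953189	1	0.651	rs2245717	0.86	0.4	SYS1	hsa-miR-150	T/G	-0.704	8mer	49	L, F
rs1443512	6.00E-16	Waist-hip ratio	20935629	0.81	0.581	rs4759058	0.78		HOXC13	hsa-miR-503	C/A	-0.755	7mer-m8	29	NS
rs504963	2.00E-08	Crohn's disease	20570966	1	0.5968	rs485073	0.63	NA	FUT2	hsa-miR-186	A/G	-1.181	7mer-m8	63	NA
rs281379	7.00E-12		21102463	0.9
rs504963	2.00E-08	Crohn's disease	20570966	1	0.5968	rs603985	0.63	NA	FUT2	hsa-miR-186	T/C	-1.181	7mer-m8	63	NA
rs281379	7.00E-12		21102463	0.9
rs10923931	4.00E-08	Type 2 diabetes	18372903	1	0.5784	rs835576	0.07		NOTCH2	hsa-miR-218	T/C	-0.718	8mer	31	F, L
rs1295686	1.00E-07	Asthma	20860503	0.96	0.581	rs847	0.76	0.31	IL13	hsa-miR-381	T/C	-1.159	7mer-m8	33	F
rs20541	5.00E-15	Psoriasis	19169254	0.96
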