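rsid	disease_flag	chrom	pos	major	minor	freq	freq_panel	site_type	pos_in_mre	mir	gene	pmid
rs3783620	0	1	101204463	G	A	.005	YRI.P1	8-mer	7	hsa-miR-126	VCAM1	18227515
rs1059479	0	1	113243892	T	G	.01	CEPH	8-mer	1	hsa-miR-138	RHOC	20232393
rs12392	0	2	198351529	G	A	NA		7-8mer	2	hsa-miR-1	HSPD1	17715156
rs5186	1	3	148459988	A	C	.306	CEU.P1	7-8mer	4	hsa-miR-155	AGTR1	16675453
rs56109847	1	3	183824557	G	A	.992	CEU.P1-LC	8-mer	4	hsa-miR-510	HTR3E	18614545
rs3731563	0	3	48199695	T	C	.017	GIH	8-mer	8	hsa-miR-21	CDC25A	19826040
rs1434536	1	4	96075965	C	T	.545	TSC-CSHL	7-8mer	1	hsa-miR-125b	BMPR1B	19738052
rs6875894	0	5	112179965	C	T	.027	YRI	7-8mer	4	hsa-miR-135b	APC	18632633
rs6875894	0	5	112179965	C	T	.027	YRI	7-8mer	5	hsa-miR-135a	APC	18632633
rs79468771	0	6	135539805	T	A	NA		8-mer	7	hsa-miR-15a	MYB	18818396
rs33986155	0	6	152420685	C	G	.083	CEU.P1	7-8mer	8	hsa-miR-206	ESR1	17312270
rs11551509	0	6	34505633	C	A	NA		8-mer	8	hsa-miR-510	SPDEF	18922924
rs8829	0	7	148504618	A	C	1	CEPH	8-mer	2	hsa-miR-101	EZH2	20478051
rs78899540	0	7	27181092	A	C	.04	YRI.P1	7-mer-A1	2	hsa-miR-130a	HOXA5	17957028
rs117556949	0	7	27194074	T	C	.992	CEU.P1-LC	8-mer	8	hsa-miR-196a	HOXA7	15105502
rs12720208	1	8	16850399	G	A	.125	CEU.P1	8-mer	6	hsa-miR-433	FGF20	18252210
rs78202059	0	8	26228382	G	T	.144	YRI.P1-LC	7-mer-A1	8	hsa-miR-222	PPP2R2A	20103675
rs1058153	0	2	46987391	C	T	NA		8-mer	2	hsa-miR-21	SOCS5	17991735
rs72808106	0	10	74035161	A	G	NA		7-mer-A1	4	hsa-miR-221	DDIT4	20018759
rs16917496	1	12	123893830	C	T	.22	CEPH	7-mer-A1	2	hsa-miR-502-5p	SET8	19789321
rs111842797	1	12	123893831	A	G	NA		7-mer-A1	8	hsa-miR-502-5p	SET8	19789321
rs76290581	0	12	6760093	T	C	.051	YRI.P1-LC	8-mer	1	hsa-miR-650	ING4	20381459
rs77080081	0	15	40382144	A	G	.014	CEU.P1	7-8mer	1	hsa-miR-125b	BMF	19471102
rs28521337	1	15	88521280	C	G	.467	CEU.P1	8-mer	8	hsa-miR-485-3p	NTRK3	19370765
rs72481816	0	15	88521572	G	C	NA		8-mer	8	hsa-miR-765	NTRK3	19370765
rs72481814	0	15	88522372	T	C	NA		7-8mer	4	hsa-miR-509-3p	NTRK3	19370765
rs28574753	0	16	28109760	G	A	.076	YRI-P1	7-8mer	2	hsa-miR-122	XPO6	19296470
rs75817141	0	17	12044581	C	T	.02	YRI.P1	7-8mer	1	hsa-miR-15b	MKK4	19861690
rs62062994	0	17	48261978	G	T	NA		8-mer	3	hsa-miR-29c	COL1A1	18390668
rs3218074	0	19	30315176	A	G	.01	PDR90	8-mer	8	hsa-miR-15b	CCNE1	18701644
rs3218074	0	19	30315176	A	G	.01	PDR90	8-mer	8	hsa-miR-16	CCNE1	18701644
rs6094029	0	20	43356176	C	T	0		7-8mer	7	hsa-miR-449a	WISP2	19351815
rs78301106	0	20	62522710	C	G	.045	CHB+JPT.P1	8-mer	7	hsa-miR-122	TPD52L2	19296470
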