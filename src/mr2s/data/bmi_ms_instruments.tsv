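snp_id	gene	chrom	effect_allele	eaf	beta_bmi	pvalue_bmi	or_ms	ci_low_ms	ci_high_ms	pvalue_ms	source	proxy_id	proxy_r2
rs1558902	FTO	16	A	0.42	0.082	7.5e-153	1.00	0.97	1.04	0.87	Immunochip	NA	1.00
rs6567160	MC4R	18	C	0.24	0.056	3.9e-53	1.00	0.96	1.04	0.97	Immunochip	rs17782313	0.99
rs13021737	TMEM18	2	G	0.83	0.060	1.1e-50	1.05	1.01	1.10	0.016	Immunochip	rs6548238	0.99
rs10938397	GNPDA2	4	G	0.43	0.040	3.2e-38	1.02	0.99	1.05	0.28	Immunochip	NA	1.00
rs543874	SEC16B	1	G	0.19	0.048	2.6e-35	1.00	0.96	1.05	0.86	WTCCC2	rs633715	0.95
rs2207139	TFAP2B	6	G	0.18	0.045	4.1e-29	1.04	0.99	1.08	0.11	Immunochip	rs987237	0.92
rs11030104	BDNF	11	A	0.79	0.041	5.6e-28	1.03	0.99	1.08	0.16	WTCCC2	NA	1.00
rs3101336	NEGR1	1	C	0.61	0.033	2.7e-26	0.99	0.96	1.03	0.73	Immunochip	rs2815752	1.00
rs7138803	BCDIN3D	12	A	0.38	0.032	8.2e-24	1.02	0.98	1.06	0.31	WTCCC2	NA	1.00
rs10182181	ADCY3	2	G	0.46	0.031	8.8e-24	1.06	1.02	1.09	8.8e-4	Immunochip	NA	1.00
rs3888190	ATP2A1	16	A	0.40	0.031	3.1e-23	1.01	0.97	1.04	0.69	Immunochip	NA	1.00
rs1516725	ETV5	3	G	0.87	0.045	1.9e-22	1.02	0.97	1.08	0.41	WTCCC2	rs6809651	0.99
rs12446632	GPRC5B	16	G	0.87	0.040	1.5e-18	1.06	1.00	1.12	0.038	WTCCC2	NA	1.00
rs2287019	QPCTL	19	C	0.80	0.036	4.6e-18	1.05	1.00	1.09	0.037	WTCCC2	NA	1.00
rs16951275	MAP2K5	15	T	0.78	0.031	1.9e-17	0.99	0.95	1.03	0.53	Immunochip	rs28670272	0.98
rs3817334	MTCH2	11	T	0.41	0.026	5.2e-17	0.97	0.94	1.01	0.14	WTCCC2	rs7124681	0.99
rs2112347	POC5	5	T	0.63	0.026	6.2e-17	1.02	0.98	1.05	0.38	Immunochip	rs34358	0.85
rs12566985	FPGT-TNNI3K	1	G	0.45	0.024	3.3e-15	0.99	0.96	1.03	0.76	WTCCC2	rs6604872	1.00
rs3810291	ZC3H4	19	A	0.67	0.028	4.8e-15	0.97	0.94	1.01	0.11	Immunochip	rs10408163	1.00
rs7141420	NRXN3	14	T	0.53	0.024	1.2e-14	1.02	0.99	1.06	0.21	WTCCC2	NA	1.00
rs13078960	CADM2	3	G	0.20	0.030	1.7e-14	0.99	0.95	1.04	0.69	WTCCC2	rs7622475	0.99
rs10968576	LINGO2	9	G	0.32	0.025	6.6e-14	1.01	0.97	1.05	0.54	WTCCC2	NA	1.00
rs12429545	OLFM4	13	A	0.13	0.033	1.1e-12	1.01	0.96	1.06	0.79	WTCCC2	NA	1.00
rs12286929	CADM1	11	G	0.52	0.022	1.3e-12	0.99	0.95	1.03	0.57	WTCCC2	rs12421648	0.84
rs11165643	PTBP2	1	T	0.58	0.022	2.1e-12	1.01	0.97	1.05	0.69	WTCCC2	NA	1.00
rs7903146	TCF7L2	10	C	0.71	0.023	1.1e-11	0.98	0.95	1.02	0.35	WTCCC2	NA	1.00
rs10132280	STXBP6	14	C	0.68	0.023	1.1e-11	1.00	0.96	1.03	0.84	Immunochip	rs12432376	0.84
rs17405819	HNF4G	8	T	0.70	0.022	2.1e-11	0.99	0.95	1.03	0.71	WTCCC2	rs2977345	0.97
rs1016287	LINC01122	2	T	0.29	0.023	2.3e-11	1.03	0.99	1.07	0.11	WTCCC2	rs759250	1.00
rs4256980	TRIM66	11	G	0.65	0.021	2.9e-11	0.99	0.95	1.03	0.69	WTCCC2	rs2316901	0.99
rs17094222	HIF1AN	10	C	0.21	0.025	5.9e-11	1.01	0.97	1.06	0.58	WTCCC2	rs17113301	0.90
rs12401738	FUBP1	1	A	0.35	0.021	1.2e-10	1.01	0.97	1.04	0.63	Immunochip	rs4130548	1.00
rs7599312	ERBB4	2	G	0.72	0.022	1.2e-10	1.02	0.98	1.07	0.24	WTCCC2	NA	1.00
rs2365389	FHIT	3	C	0.58	0.020	1.6e-10	0.98	0.94	1.02	0.29	WTCCC2	rs7629340	0.98
rs205262	C6orf106	6	G	0.27	0.022	1.8e-10	1.01	0.97	1.05	0.62	Immunochip	NA	1.00
rs2820292	NAV1	1	C	0.56	0.020	1.8e-10	1.03	0.99	1.07	0.11	WTCCC2	rs1032524	0.93
rs12885454	PRKD1	14	C	0.64	0.021	1.9e-10	1.01	0.98	1.05	0.42	WTCCC2	rs1307813	1.00
rs12016871	MTIF3	13	T	0.20	0.030	2.3e-10	1.01	0.97	1.06	0.58	WTCCC2	rs1885989	0.82
rs16851483	RASA2	3	T	0.07	0.048	3.6e-10	1.02	0.95	1.09	0.63	WTCCC2	rs2640017	0.99
rs1167827	HIP1	7	G	0.55	0.020	6.3e-10	1.00	0.97	1.04	0.93	Immunochip	NA	1.00
rs758747	NLRC3	16	T	0.27	0.023	7.5e-10	1.03	0.99	1.07	0.16	WTCCC2	NA	1.00
rs1928295	TLR4	9	T	0.55	0.019	7.9e-10	1.02	0.99	1.06	0.25	WTCCC2	NA	1.00
rs9925964	KAT8	16	A	0.62	0.019	8.1e-10	1.02	0.98	1.05	0.36	Immunochip	NA	1.00
rs11126666	KCNK3	2	A	0.28	0.021	1.3e-9	1.02	0.99	1.06	0.25	Immunochip	NA	1.00
rs2650492	SBK1	16	A	0.30	0.021	1.9e-9	1.01	0.98	1.05	0.58	Immunochip	NA	1.00
rs6804842	RARB	3	G	0.58	0.019	2.5e-9	1.03	0.99	1.07	0.15	WTCCC2	NA	1.00
rs12940622	RPTOR	17	G	0.58	0.018	2.5e-9	1.01	0.97	1.05	0.58	WTCCC2	NA	1.00
rs4740619	C9orf93	9	T	0.54	0.018	4.6e-9	1.00	0.96	1.04	0.86	WTCCC2	NA	1.00
rs13191362	PARK2	6	A	0.88	0.028	7.3e-9	1.01	0.95	1.07	0.83	WTCCC2	rs13202339	0.98
rs3736485	DMXL2	15	A	0.45	0.018	7.4e-9	0.97	0.94	1.00	0.11	Immunochip	rs4775961	0.88
rs17001654	SCARB2	4	G	0.15	0.031	7.7e-9	1.04	1.00	1.09	0.089	Immunochip	rs17001561	0.95
rs11191560	NT5C2	10	C	0.09	0.031	8.5e-9	0.98	0.93	1.04	0.58	Immunochip	NA	1.00
rs1528435	UBE2E3	2	T	0.63	0.018	1.2e-8	1.00	0.97	1.04	0.83	WTCCC2	rs6727573	0.95
rs2075650	TOMM40	19	A	0.85	0.026	1.3e-8	1.03	0.98	1.08	0.21	Immunochip	NA	1.00
rs1000940	RABEP1	17	G	0.32	0.019	1.3e-8	1.01	0.97	1.05	0.64	WTCCC2	NA	1.00
rs11583200	ELAVL4	1	C	0.40	0.018	1.5e-8	1.01	0.98	1.05	0.48	WTCCC2	NA	1.00
rs9400239	FOXO3	6	C	0.69	0.019	1.6e-8	0.97	0.93	1.01	0.15	WTCCC2	rs2153960	0.93
rs10733682	LMX1B	9	A	0.48	0.017	1.8e-8	1.00	0.97	1.04	0.96	WTCCC2	NA	1.00
rs11688816	EHBP1	2	G	0.53	0.017	1.9e-8	1.02	0.99	1.06	0.21	WTCCC2	rs360791	0.82
rs11057405	CLIP1	12	G	0.90	0.031	2.0e-8	1.05	0.99	1.11	0.074	Immunochip	NA	1.00
rs2121279	LRP1B	2	T	0.12	0.025	2.3e-8	1.02	0.96	1.08	0.53	WTCCC2	rs6714473	0.80
rs29941	KCTD15	19	G	0.67	0.018	2.4e-8	1.00	0.97	1.04	0.86	Immunochip	NA	1.00
rs3849570	GBE1	3	A	0.36	0.019	2.6e-8	1.00	0.96	1.03	0.86	Immunochip	rs3860595	0.88
rs6477694	EPB41L4B	9	C	0.37	0.017	2.7e-8	1.02	0.98	1.05	0.33	Immunochip	NA	1.00
rs2176598	HSD17B12	11	T	0.25	0.020	3.0e-8	1.03	0.99	1.07	0.16	WTCCC2	rs7110437	0.81
rs7899106	GRID1	10	G	0.05	0.040	3.0e-8	1.06	0.98	1.15	0.15	WTCCC2	rs11201714	1.00
rs17724992	PGPEP1	19	A	0.75	0.019	3.4e-8	1.02	0.98	1.06	0.34	WTCCC2	NA	1.00
rs7243357	GRP	18	T	0.81	0.022	3.9e-8	0.99	0.95	1.04	0.70	WTCCC2	rs9961404	0.90
rs1808579	C18orf8	18	C	0.53	0.017	4.2e-8	1.00	0.96	1.04	0.91	WTCCC2	NA	1.00
rs2033732	RALYL	8	C	0.75	0.019	4.9e-8	1.00	0.96	1.04	0.83	WTCCC2	rs733594	0.91
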