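transcript_id	symbol	fc_2c	fc_3c	fc_4c	fc_5c	fc_9c	fc_30c	housekeeping
AB032956	GALNTL1	-0.57	-0.20	0.16	-0.13	0.02	0.09	0
AF000424	LST1	-0.84	-0.18	-0.20	-0.05	-0.14	-0.23	0
AJ830742	AIPL1	-0.82	-0.43	-0.25	-0.24	-0.07	-0.08	0
AK058068	Klkbl4	-0.79	-0.41	-0.17	0.11	-0.15	-0.07	0
AK094115	N/A	-0.70	-0.35	-0.04	-0.01	0.01	-0.41	0
AK097834	RP5-821D11.2	-0.68	-0.31	-0.03	-0.21	-0.01	0.01	0
AK128093	N/A	-0.63	-0.28	-0.15	0.05	-0.19	-0.30	0
AL833920	C1orf167	-0.80	-0.60	0.17	-0.04	0.18	-0.22	0
AY358368	CDHR5	-0.63	-0.23	-0.09	-0.10	-0.19	-0.25	0
AY358413	N/A	-0.71	-0.15	0.10	0.04	0.10	-0.28	0
BC016964	MRGPRF	-0.55	-0.08	-0.12	-0.02	0.06	0.07	0
BC020658	TMEM40	-0.70	-0.56	-0.15	-0.15	0.04	-0.12	0
BC039318	BIRC8	-0.76	-0.42	-0.10	-0.09	0.09	-0.02	0
BC042847	LOC150763	-0.51	-0.29	-0.12	0.01	-0.03	-0.03	0
BC071746	CLEC7A	-0.54	-0.32	-0.12	-0.17	0.14	0.17	0
BC101635	NKX6-2	-0.53	-0.56	-0.12	-0.12	-0.14	-0.12	0
BC104999	CASR	-0.59	-0.17	-0.25	0.08	0.06	-0.30	0
NM_000066	C8B	-0.53	-0.07	0.00	-0.07	-0.03	-0.23	0
NM_001001711	DDI1	-0.56	-0.21	-0.27	-0.31	-0.17	-0.26	0
NM_001001923	OR5C1	-0.71	-0.28	-0.22	0.08	-0.13	-0.24	0
NM_001003397	TPD52L1	-0.62	-0.31	-0.33	-0.18	0.04	-0.31	0
NM_001004726	OR4X1	-0.83	-0.34	0.07	0.03	-0.11	-0.18	0
NM_001427	EN2	-0.51	-0.33	-0.22	-0.06	0.02	-0.13	0
NM_003857	GALR2	-0.55	-0.31	-0.13	0.02	-0.01	-0.13	0
NM_004244	CD163	-0.63	-0.30	-0.20	-0.13	0.04	-0.25	0
NM_005205	COX6A2	-0.64	-0.39	-0.38	-0.07	-0.30	-0.17	0
NM_005298	GPR25	-0.75	-0.41	0.02	-0.05	-0.02	0.02	0
NM_006686	ACTL7B	-0.55	-0.44	-0.13	-0.02	-0.01	-0.15	0
NM_012377	OR7C2	-0.77	-0.22	-0.03	-0.14	-0.14	-0.03	0
NM_014270	SLC7A9	-0.62	-0.16	-0.20	0.01	-0.27	-0.19	0
NM_018404	ADAP2	-0.75	-0.40	-0.30	-0.19	0.04	0.03	0
NM_018965	TREM2	-0.69	-0.34	-0.08	-0.14	0.09	-0.20	0
NM_138784	RP11-45 J16.2	-0.58	-0.29	0.06	-0.05	0.20	-0.17	0
NM_145898	CCL23	-0.55	0.03	-0.09	-0.20	0.02	-0.20	0
NM_170685	TAC4	-0.67	-0.30	-0.19	-0.06	-0.13	-0.24	0
NM_182510	FLJ32252	-0.52	-0.33	-0.26	-0.10	-0.10	0.02	0
NM_198690	KRTAP10-9	-0.73	-0.29	-0.10	-0.03	-0.28	-0.13	0
NM_206895	UNQ830	-0.62	-0.45	-0.22	-0.25	-0.10	-0.18	0
NM_207478	FLJ44385	-0.68	-0.12	-0.10	-0.08	-0.01	-0.26	0
X04876	MPO	-0.72	-0.36	-0.20	0.19	-0.01	-0.16	0
XM_375090	FLJ44817	-0.62	-0.58	-0.16	0.00	-0.27	-0.11	0
XM_497769	LOC644280	-0.58	-0.19	-0.20	-0.02	-0.07	-0.05	0
XM_499305	LOC441239	-0.63	-0.31	-0.21	-0.08	-0.15	-0.24	0
XM_927256	LOC644003	-0.54	-0.57	-0.31	-0.19	-0.27	-0.10	0
XM_929203	LOC646258	-0.51	-0.20	-0.38	-0.13	-0.11	-0.08	0
XM_931594	LOC643514	-0.54	-0.23	-0.11	-0.01	-0.21	-0.16	0
XM_931993	LOC644065	-0.65	-0.29	-0.15	0.05	-0.06	-0.21	0
XM_934559	LOC647240	-0.60	-0.40	-0.23	-0.16	-0.08	-0.08	0
XM_935431	LOC374569	-0.54	-0.31	-0.14	-0.12	-0.13	-0.10	0
AK130941	KIAA0825	0.63	0.30	-0.07	-0.07	-0.06	0.15	0
NM_001001789	C21orf24	0.52	0.19	0.08	-0.01	0.00	0.21	0
NM_001024603	LOC154872	0.51	0.13	0.15	0.05	0.06	0.21	0
NM_001890	CSN1S1	0.57	-0.04	0.03	0.30	-0.07	0.11	0
NM_018431	DOK5	0.56	0.04	0.03	0.01	-0.02	0.31	0
NM_020482	FHL5	0.55	0.38	0.01	0.10	-0.02	-0.08	0
NM_020778	ALPK3	0.76	0.45	0.23	0.16	0.03	0.19	0
BC001601	GAPDH	0.01	0.09	0.02	0.10	0.03	0.04	1
NM_002046	GAPDH	0.09	-0.14	-0.02	-0.10	-0.01	0.00	1
BC009081	GAPDH	0.01	-0.05	0.01	-0.04	-0.04	-0.03	1
NM_001101	ACTB	-0.04	-0.05	-0.05	0.05	0.02	0.00	1
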