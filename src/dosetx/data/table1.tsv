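gene_id	transcript_id	symbol	log2fc	dispersion	adj_p	description
7940	AF000424	LST1	-0.84	0.14	0.04	Leukocyte specific transcript 1
390113	NM_001004726	OR4X1	-0.83	0.06	0.01	Olfactory receptor, family 4, subfamily X, member 1
23746	AJ830742	AIPL1	-0.82	0.16	0.04	Aryl hydrocarbon receptor interacting protein-like 1
284498	AL833920	C1orf167	-0.80	0.17	0.05	Chromosome 1 open reading frame 167
221191	AK058068	Klkbl4	-0.79	0.12	0.04	Plasma kallikrein-like protein 4
26658	NM_012377	OR7C2	-0.77	0.07	0.01	Olfactory receptor, family 7, subfamily C, member 2
112401	BC039318	BIRC8	-0.76	0.11	0.00	Baculoviral IAP repeat-containing 8
2848	NM_005298	GPR25	-0.75	0.15	0.02	G protein-coupled receptor 25
55803	NM_018404	ADAP2	-0.75	0.11	0.02	ArfGAP with dual PH domains 2
386676	NM_198690	KRTAP10-9	-0.73	0.12	0.04	Keratin associated protein 10-9
4353	X04876	MPO	-0.72	0.15	0.04	Myeloperoxidase
N/A	AY358413	N/A	-0.71	0.18	0.02	Homo sapiens clone DNA59853 trypsin inhibitor
392391	NM_001001923	OR5C1	-0.71	0.05	0.04	Olfactory receptor, family 5, subfamily C, member 1
N/A	AK094115	N/A	-0.70	0.11	0.04	Homo sapiens cDNA FLJ36796 fis, clone ADRGL2006817
55287	BC020658	TMEM40	-0.70	0.15	0.02	Transmembrane protein 40
54209	NM_018965	TREM2	-0.69	0.10	0.02	Triggering receptor expressed on myeloid cells 2
150365	AK097834	RP5-821D11.2	-0.68	0.17	0.02	Similar to mouse meiosis defective 1 gene
400934	NM_207478	FLJ44385	-0.68	0.09	0.04	FLJ44385 protein
255061	NM_170685	TAC4	-0.67	0.14	0.01	Tachykinin 4 (hemokinin)
644065	XM_931993	LOC644065	-0.65	0.23	0.04	Hypothetical protein LOC644065
1339	NM_005205	COX6A2	-0.64	0.17	0.01	Cytochrome c oxidase subunit VIa polypeptide 2
N/A	AK128093	N/A	-0.63	0.09	0.04	Homo sapiens cDNA FLJ46214 fis, clone TESTI4012623.
53841	AY358368	CDHR5	-0.63	0.11	0.04	Mucin-like protocadherin
9332	NM_004244	CD163	-0.63	0.18	0.03	CD163 molecule
441239	XM_499305	LOC441239	-0.63	0.22	0.05	Hypothetical gene supported by BC063653
7164	NM_001003397	TPD52L1	-0.62	0.09	0.02	Tumor protein D52-like 1
11136	NM_014270	SLC7A9	-0.62	0.09	0.04	Solute carrier family 7 member 9
389084	NM_206895	UNQ830	-0.62	0.11	0.04	ASCL830
400224	XM_375090	FLJ44817	-0.62	0.20	0.04	Similar to pleckstrin homology domain protein (5 V327)
647240	XM_934559	LOC647240	-0.60	0.06	0.00	Hypothetical protein LOC647240
846	BC104999	CASR	-0.59	0.06	0.00	Calcium-sensing receptor
116123	NM_138784	RP11-45 J16.2	-0.58	0.09	0.04	Flavin-containing monooxygenase pseudogene
644280	XM_497769	LOC644280	-0.58	0.06	0.05	Hypothetical protein LOC644280
57452	AB032956	GALNTL1	-0.57	0.17	0.05	Alpha-D-galactosamine N-acetylgalactosaminyltransferase
414301	NM_001001711	DDI1	-0.56	0.11	0.04	DDI1, DNA-damage inducible 1, homolog 1 (S. cerevisiae)
116535	BC016964	MRGPRF	-0.55	0.17	0.01	MAS-related GPR, member F
8811	NM_003857	GALR2	-0.55	0.07	0.04	Galanin receptor 2
10880	NM_006686	ACTL7B	-0.55	0.12	0.04	Actin-like 7B
6368	NM_145898	CCL23	-0.55	0.11	0.05	Chemokine (C-C motif) ligand 23
64581	BC071746	CLEC7A	-0.54	0.08	0.04	C-type lectin domain family 7, member A
644003	XM_927256	LOC644003	-0.54	0.11	0.04	Similar to Mucin-2 precursor (Intestinal mucin 2)
643514	XM_931594	LOC643514	-0.54	0.10	0.03	Hypothetical protein LOC643514
374569	XM_935431	LOC374569	-0.54	0.07	0.04	Similar to Lysophospholipase
84504	BC101635	NKX6-2	-0.53	0.13	0.03	NK6 transcription factor related, locus 2 (Drosophila)
732	NM_000066	C8B	-0.53	0.06	0.05	Complement component 8, beta polypeptide
146336	NM_182510	FLJ32252	-0.52	0.03	0.01	Hypothetical protein FLJ32252
150763	BC042847	LOC150763	-0.51	0.10	0.04	Hypothetical protein LOC150763
2020	NM_001427	EN2	-0.51	0.08	0.04	Engrailed homolog 2
646258	XM_929203	LOC646258	-0.51	0.11	0.04	Hypothetical protein LOC646258
154872	NM_001024603	LOC154872	0.51	0.10	0.03	Hypothetical LOC154872
400866	NM_001001789	C21orf24	0.52	0.12	0.05	Chromosome 21 open reading frame 24
9457	NM_020482	FHL5	0.55	0.19	0.04	Four and a half LIM domains 5
55816	NM_018431	DOK5	0.56	0.04	0.03	Docking protein 5
1446	NM_001890	CSN1S1	0.57	0.09	0.04	Casein alpha s1
285600	AK130941	KIAA0825	0.63	0.06	0.01	KIAA0825 protein
57538	NM_020778	ALPK3	0.76	0.10	0.01	Alpha-kinase 3
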