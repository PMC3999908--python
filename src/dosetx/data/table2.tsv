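symbol	gene_id	ma_r1	ma_r2	ma_r3	ma_mean	ma_sem	pcr_r1	pcr_r2	pcr_r3	pcr_mean	pcr_sem
AIPL1	23746	-0.60	-0.59	-1.06	-0.75	0.13	n.d.	n.d.	n.d.
ALPK3	57538	1.16	0.04	0.96	0.72	0.28	-0.87	0.24	-0.25	-0.29	0.26
BIRC8	112401	-0.79	-0.77	-0.91	-0.82	0.04	1.64	-1.12	-1.43	-0.30	0.80
C1ORF167	284498	-0.69	-0.51	-1.00	-0.73	0.12	n.d.	n.d.	n.d.
DDI1	414301	-0.93	0.02	-1.30	-0.74	0.32	-0.62	0.16	-1.23	-0.56	0.33
EN2	2020	-0.62	-0.13	-0.77	-0.51	0.16	-1.53	-0.12	-0.41	-0.69	0.35
GALR2	8811	-0.57	-0.36	-0.72	-0.55	0.08	-0.94	-0.19	-0.61	-0.58	0.18
GPR25	2848	-1.15	0.20	-1.08	-0.68	0.36	-0.74	0.60	-0.11	-0.08	0.32
LST1	221191	-0.71	-0.76	-1.18	-0.88	0.12	n.d.	n.d.	n.d.
OR4X1	7940	-0.96	-0.55	-0.74	-0.75	0.10	n.d.	n.d.	n.d.
OR5C1	390113	-0.84	-0.33	-0.79	-0.66	0.13	-0.95	-0.51	-1.00	-0.82	0.13
Klkbl4	392391	-0.05	-0.70	-1.04	-0.60	0.24	-1.10	-0.17	-0.41	-0.56	0.23
TAC4	255061	-0.23	-0.28	-1.34	-0.62	0.30	-1.14	-0.10	-0.46	-0.57	0.25
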