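# Chromosomes III, VII, VIII map distances, isogenic SK1 NHY942/943 background.
# Same schema as table5.tsv. Chromosome VII interval headings printed as
# "TRP5-CYH2", "CYH2-MET1:" and "MET13-LYS5:"; the latter two are normalized to
# CYH2-MET13 and MET13-LYS5.
# The mlh3Δ mms4Δ CEN3-MAT single-spore cM cell is printed 8.5, which contradicts
# its own counts (48/1336 = 3.6) and equals the chromosome-III single-spore
# cumulative (2.4 + 2.5 + 3.6); the count-implied 3.6 is stored.
genotype	chromosome	interval	spores_total	parental	recombinant	cm_single	tetrads	PD	TT	NPD	ci_low	ci_high
wild type	III	HIS4-LEU2	2711	2360	351	12.9	572	413	141	2	12.6	15.0
mlh3Δ	III	HIS4-LEU2	1453	1333	120	8.3	306	253	47	1	7.4	10.3
mms4Δ	III	HIS4-LEU2	555	508	47	8.5	32	21	5	0	5.8	13.5
mlh3Δ mms4Δ	III	HIS4-LEU2	1336	1304	32	2.4	170	158	2	0	0.2	1.1
wild type	III	LEU2-CEN3	2711	2527	184	6.8	572	488	68	0	5.4	6.8
mlh3Δ	III	LEU2-CEN3	1453	1314	139	9.6	306	261	39	1	6.1	8.9
mms4Δ	III	LEU2-CEN3	555	482	73	13.2	32	22	3	1	5.8	28.8
mlh3Δ mms4Δ	III	LEU2-CEN3	1336	1302	34	2.5	170	156	4	0	0.6	1.9
wild type	III	CEN3-MAT	2711	2309	402	14.8	572	395	160	1	13.9	15.9
mlh3Δ	III	CEN3-MAT	1453	1246	207	14.2	306	223	78	0	11.7	14.2
mms4Δ	III	CEN3-MAT	555	464	91	16.4	32	23	3	0	2.6	8.9
mlh3Δ mms4Δ	III	CEN3-MAT	1336	1288	48	3.6	170	153	6	1	1.8	5.8
wild type	VII	TRP5-CYH2	2711	1803	908	33.5	572	197	337	9	34.2	37.8
mlh3Δ	VII	TRP5-CYH2	1453	1215	238	16.4	306	198	100	0	15.4	18.2
mms4Δ	VII	TRP5-CYH2	555	391	164	29.5	32	11	11	0	19.7	30.3
mlh3Δ mms4Δ	VII	TRP5-CYH2	1336	1289	47	3.5	170	151	11	0	2.4	4.4
wild type	VII	CYH2-MET13	2711	2451	260	9.6	572	442	101	0	8.5	10.1
mlh3Δ	VII	CYH2-MET13	1453	1350	103	7.1	306	266	32	0	4.5	6.3
mms4Δ	VII	CYH2-MET13	555	500	55	9.9	32	18	4	0	5.0	13.2
mlh3Δ mms4Δ	VII	CYH2-MET13	1336	1302	34	2.5	170	156	6	0	1.1	3.0
wild type	VII	MET13-LYS5	2711	2152	559	20.6	572	334	205	4	19.6	22.6
mlh3Δ	VII	MET13-LYS5	1453	1307	146	10.0	306	242	55	1	8.7	11.7
mms4Δ	VII	MET13-LYS5	555	461	94	16.9	32	15	7	0	10.9	20.9
mlh3Δ mms4Δ	VII	MET13-LYS5	1336	1271	65	4.9	170	148	14	0	3.2	5.4
wild type	VIII	CEN8-THR1	2711	2105	606	22.4	572	317	219	2	20.2	22.8
mlh3Δ	VIII	CEN8-THR1	1453	1305	148	10.2	306	251	45	0	6.6	8.6
mms4Δ	VIII	CEN8-THR1	555	463	92	16.6	32	16	6	0	8.9	18.4
mlh3Δ mms4Δ	VIII	CEN8-THR1	1336	1288	48	3.6	170	157	3	0	0.4	1.5
wild type	VIII	THR1-CUP1	2711	2043	668	24.6	572	277	260	1	23.5	25.9
mlh3Δ	VIII	THR1-CUP1	1453	1258	195	13.4	306	226	69	1	11.1	14.2
mms4Δ	VIII	THR1-CUP1	555	427	128	23.1	32	14	8	0	13.1	23.3
mlh3Δ mms4Δ	VIII	THR1-CUP1	1336	1292	44	3.3	170	154	6	0	1.1	2.6
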