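# Chromosome XV map distances, congenic SK1 EAY1108/1112 background.
# Single-spore columns: spores_total = parental + recombinant; cm_single = 100*recombinant/spores_total (printed, 1 dp).
# Tetrad columns: tetrads = complete (4-spore-viable) tetrads; PD/TT/NPD as printed; ci_low/ci_high = printed 95% CI of the Perkins estimate.
genotype	chromosome	interval	spores_total	parental	recombinant	cm_single	tetrads	PD	TT	NPD	ci_low	ci_high
wild type	XV	URA3-LEU2	4644	3635	1009	21.7	1068	607	456	5	21.8	23.8
msh5Δ	XV	URA3-LEU2	5674	5352	322	5.7	757	643	76	1	5.0	6.4
mlh3Δ	XV	URA3-LEU2	3023	2682	341	11.3	582	460	114	8	12.3	15.5
msh5Δ mlh3Δ	XV	URA3-LEU2	382	352	30	7.9	43	34	8	0	6.5	12.6
msh5-D76A	XV	URA3-LEU2	351	310	41	11.7	77	57	17	0	9.0	13.9
msh5-T423A	XV	URA3-LEU2	457	378	79	17.3	101	62	33	0	14.9	19.8
mlh3-R96A	XV	URA3-LEU2	840	676	164	19.5	177	105	69	0	18.0	21.7
mlh3-G97A	XV	URA3-LEU2	978	841	137	14.0	210	152	55	2	13.6	18.5
msh5-D76A mlh3-R96A	XV	URA3-LEU2	462	409	53	11.5	81	63	16	0	7.9	12.4
msh5-D76A mlh3-G97A	XV	URA3-LEU2	490	455	35	7.1	82	71	11	0	4.8	8.6
msh5-T423A mlh3-R96A	XV	URA3-LEU2	717	583	134	18.7	160	96	64	0	18.1	21.9
msh5-T423A mlh3-G97A	XV	URA3-LEU2	622	552	70	11.3	130	100	28	1	10.3	16.1
wild type	XV	LEU2-LYS2	4644	3388	1256	27.0	1068	496	569	3	26.6	28.4
msh5Δ	XV	LEU2-LYS2	5674	5047	627	11.1	757	562	155	3	11.0	13.0
mlh3Δ	XV	LEU2-LYS2	3023	2610	413	13.7	582	424	154	3	12.9	16.6
msh5Δ mlh3Δ	XV	LEU2-LYS2	382	338	44	11.5	43	31	10	1	11.5	26.6
msh5-D76A	XV	LEU2-LYS2	351	308	43	12.3	77	58	16	0	8.4	13.2
msh5-T423A	XV	LEU2-LYS2	457	365	92	20.1	101	57	38	0	17.5	22.5
mlh3-R96A	XV	LEU2-LYS2	840	695	145	17.3	177	112	62	0	16.0	19.6
mlh3-G97A	XV	LEU2-LYS2	978	825	153	15.6	210	140	68	1	15.6	19.8
msh5-D76A mlh3-R96A	XV	LEU2-LYS2	462	422	40	8.7	81	67	12	0	5.6	9.6
msh5-D76A mlh3-G97A	XV	LEU2-LYS2	490	457	33	6.7	82	72	10	0	4.3	7.9
msh5-T423A mlh3-R96A	XV	LEU2-LYS2	717	606	111	15.5	160	111	49	0	13.5	17.1
msh5-T423A mlh3-G97A	XV	LEU2-LYS2	622	535	87	14.0	130	91	37	1	13.7	19.6
wild type	XV	LYS2-ADE2	4644	4052	592	12.7	1068	803	263	2	12.1	13.7
msh5Δ	XV	LYS2-ADE2	5674	5409	265	4.7	757	659	61	0	3.7	4.7
mlh3Δ	XV	LYS2-ADE2	3023	2822	201	6.6	582	501	81	0	6.2	7.7
msh5Δ mlh3Δ	XV	LYS2-ADE2	382	363	19	5.0	43	39	3	0	1.6	5.6
msh5-D76A	XV	LYS2-ADE2	351	320	31	8.8	77	60	14	0	7.2	11.7
msh5-T423A	XV	LYS2-ADE2	457	405	52	11.4	101	75	20	0	8.4	12.6
mlh3-R96A	XV	LYS2-ADE2	840	775	65	7.7	177	149	25	0	5.9	8.5
mlh3-G97A	XV	LYS2-ADE2	978	898	80	8.2	210	173	35	1	7.9	11.7
msh5-D76A mlh3-R96A	XV	LYS2-ADE2	462	437	25	5.4	81	68	11	0	5.0	8.9
msh5-D76A mlh3-G97A	XV	LYS2-ADE2	490	464	26	5.3	82	75	7	0	2.7	5.8
msh5-T423A mlh3-R96A	XV	LYS2-ADE2	717	669	48	6.7	160	141	19	0	4.7	7.2
msh5-T423A mlh3-G97A	XV	LYS2-ADE2	622	591	31	5.0	130	116	13	0	3.7	6.4
wild type	XV	ADE2-HIS3	4644	3033	1611	34.7	1068	343	709	16	36.5	38.9
msh5Δ	XV	ADE2-HIS3	5674	4797	877	15.5	757	496	215	9	17.2	20.2
mlh3Δ	XV	ADE2-HIS3	3023	2485	538	17.8	582	379	201	2	17.1	19.5
msh5Δ mlh3Δ	XV	ADE2-HIS3	382	328	54	14.1	43	30	12	0	10.8	17.8
msh5-D76A	XV	ADE2-HIS3	351	277	74	21.1	77	43	31	0	18.1	23.8
msh5-T423A	XV	ADE2-HIS3	457	322	135	29.5	101	44	49	2	27.4	36.9
mlh3-R96A	XV	ADE2-HIS3	840	600	240	28.6	177	74	98	2	28.7	34.5
mlh3-G97A	XV	ADE2-HIS3	978	801	177	18.1	210	136	73	0	15.8	19.1
msh5-D76A mlh3-R96A	XV	ADE2-HIS3	462	395	67	14.5	81	57	20	2	14.6	25.9
msh5-D76A mlh3-G97A	XV	ADE2-HIS3	490	422	68	13.9	82	58	24	0	12.1	17.1
msh5-T423A mlh3-R96A	XV	ADE2-HIS3	717	575	142	19.8	160	97	63	0	17.8	21.6
msh5-T423A mlh3-G97A	XV	ADE2-HIS3	622	507	115	18.5	130	83	45	1	16.8	22.8
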