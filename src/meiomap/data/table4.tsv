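# Spore viability (%) and cumulative chromosome XV map distance (cM, four
# intervals, from four-spore-viable tetrads) in the EAY1108/1112 background.
# n_tetrads = number of tetrads behind the cumulative distance (printed in parentheses).
# regression_set = 1 marks the 10 strains (wild type, mlh3Δ, eight mlh3 ATPase
# alleles) of the viability-vs-distance fit.
strain	spore_viability_pct	cM	n_tetrads	regression_set
MLH3	97.0	100.9	1068	1
mlh3Δ	71.7	54.5	582	1
mlh3-E31A	89.2	67.0	330	1
mlh3-N35A	72.7	51.5	229	1
mlh3-A41F	71.6	51.2	214	1
mlh3-G63R	74.1	51.2	216	1
mlh3-K80E	71.8	49.8	221	1
mlh3-K83A	94.1	100.5	289	1
mlh3-R96A	82.4	76.4	177	1
mlh3-G97A	81.5	61.0	210	1
msh5Δ	36.0	37.0	540	0
msh5Δ mlh3Δ	31.8	38.5	43	0
msh5-D76A	87.8	53.9	77	0
msh5-T423A	95.2	78.3	101	0
msh5-D76A mlh3-R96A	57.8	45.0	81	0
msh5-D76A mlh3-G97A	47.1	31.7	82	0
msh5-T423A mlh3-R96A	89.6	60.9	160	0
msh5-T423A mlh3-G97A	78.3	54.7	130	0
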