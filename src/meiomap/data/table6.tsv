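# Spore viabilities and cumulative genetic map distances (cM) per chromosome.
# Chromosome III/VII/VIII data: NHY942/943 background; chromosome XV: EAY1108/1112.
# The second mms4Δ row is an independent earlier data set for the same genotype
# (no chromosome XV value); blank cells are empty fields.
# fold_decrease rows are printed ratios of mlh3Δ mms4Δ vs wild type.
genotype	spore_viability_pct	n_tetrads	cm_III	cm_VII	cm_VIII	cm_XV
wild type	91.0	572	34.9	68.7	46.2	96.1
mlh3Δ	79.0	306	29.3	32.4	20.3	54.5
mms4Δ	46.3	32	32.7	50.0	31.8	83.4
mms4Δ (prior data)	45.4	272	25.2	62.1	35.3
mlh3Δ mms4Δ	61.9	170	5.7	9.6	2.8	8.4
fold decrease			6.1	7.2	16.5	11.4
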