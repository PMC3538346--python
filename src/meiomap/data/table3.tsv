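# lys2::InsE-A14 reversion (fluctuation assay) results.
# median_rate_e7 and CI bounds are in units of 1e-7 mutations/cell/generation.
# relative = printed fold over the wild-type median rate (computed from
# unrounded medians in the source, hence not always equal to the ratio of the
# printed rounded medians).
# group: haploid = single-copy strains; overexpression = GAL10 dominant-negative arm.
genotype	group	n	median_rate_e7	ci_low_e7	ci_high_e7	relative	phenotype
MLH3	haploid	110	4.71	3.87	5.11	1.0	+
mlh3Δ	haploid	110	26.5	23.5	30.4	5.7	-
mlh3-E31A	haploid	15	30.5	16.7	51.6	6.5	-
mlh3-N35A	haploid	15	31.2	25.6	44.4	6.7	-
mlh3-A41F	haploid	15	27.9	17.1	34.3	6.0	-
mlh3-G63R	haploid	15	23.8	18.2	37.1	5.1	-
mlh3-K80E	haploid	15	16.0	15.1	27.7	3.4	-
mlh3-K83A	haploid	15	5.24	3.49	6.34	1.1	+
mlh3-R96A	haploid	15	14.8	6.42	40.6	3.2	-
mlh3-G97A	haploid	15	16.6	11.8	26.0	3.6	-
MLH3 + empty vector	overexpression	11	4.42	1.02	6.05	1	+
MLH3 + pGAL10-MLH3	overexpression	11	39100	15700	79900	8850	-
MLH3 + pGAL10-mlh3-E31A	overexpression	11	47800	28700	85900	10800	-
MLH3 + pGAL10-mlh3-R96A	overexpression	11	23500	5910	38400	5320	-
MLH3 + pGAL10-mlh3-G97A	overexpression	11	96000	45800	156000	21700	-
mlh1Δ + empty vector	overexpression	11	218000	121000	283000	49300	-
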