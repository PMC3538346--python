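# Aberrant (3:1 or 1:3) marker segregation, percent of four-spore-viable
# tetrads, NHY942/943 background. n_tetrads = four-spore-viable tetrads examined.
# marker "TOTAL" rows carry the printed per-chromosome total.
genotype	chromosome	n_tetrads	marker	percent_aberrant
wild type	III	572	HIS4	2.1
wild type	III	572	LEU2	0.3
wild type	III	572	ADE2	0.2
wild type	III	572	MATa	0.2
wild type	III	572	TOTAL	2.8
mlh3Δ	III	306	HIS4	0.7
mlh3Δ	III	306	LEU2	0.7
mlh3Δ	III	306	ADE2	0.3
mlh3Δ	III	306	MATa	0.0
mlh3Δ	III	306	TOTAL	1.7
mms4Δ	III	32	HIS4	9.4
mms4Δ	III	32	LEU2	6.3
mms4Δ	III	32	ADE2	3.1
mms4Δ	III	32	MATa	3.1
mms4Δ	III	32	TOTAL	21.9
mlh3Δ mms4Δ	III	170	HIS4	4.1
mlh3Δ mms4Δ	III	170	LEU2	0.6
mlh3Δ mms4Δ	III	170	ADE2	0
mlh3Δ mms4Δ	III	170	MATa	1.2
mlh3Δ mms4Δ	III	170	TOTAL	5.9
wild type	VII	572	LYS5	1.6
wild type	VII	572	MET13	2.4
wild type	VII	572	CYH2	0.3
wild type	VII	572	TRP5	0.7
wild type	VII	572	TOTAL	5.0
mlh3Δ	VII	306	LYS5	0.7
mlh3Δ	VII	306	MET13	2.0
mlh3Δ	VII	306	CYH2	0.0
mlh3Δ	VII	306	TRP5	0.0
mlh3Δ	VII	306	TOTAL	2.7
mms4Δ	VII	32	LYS5	9.4
mms4Δ	VII	32	MET13	0.0
mms4Δ	VII	32	CYH2	6.3
mms4Δ	VII	32	TRP5	0.0
mms4Δ	VII	32	TOTAL	15.7
mlh3Δ mms4Δ	VII	170	LYS5	1.2
mlh3Δ mms4Δ	VII	170	MET13	2.4
mlh3Δ mms4Δ	VII	170	CYH2	0.0
mlh3Δ mms4Δ	VII	170	TRP5	1.2
mlh3Δ mms4Δ	VII	170	TOTAL	4.8
wild type	VIII	572	URA3	0.2
wild type	VIII	572	THR1	5.1
wild type	VIII	572	CUP1	0.7
wild type	VIII	572	TOTAL	6.0
mlh3Δ	VIII	306	URA3	0.0
mlh3Δ	VIII	306	THR1	3.3
mlh3Δ	VIII	306	CUP1	0.0
mlh3Δ	VIII	306	TOTAL	3.3
mms4Δ	VIII	32	URA3	0.0
mms4Δ	VIII	32	THR1	6.3
mms4Δ	VIII	32	CUP1	9.4
mms4Δ	VIII	32	TOTAL	15.7
mlh3Δ mms4Δ	VIII	170	URA3	0.6
mlh3Δ mms4Δ	VIII	170	THR1	4.7
mlh3Δ mms4Δ	VIII	170	CUP1	0.6
mlh3Δ mms4Δ	VIII	170	TOTAL	5.9
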