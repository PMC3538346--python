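# Marker positions (kb) on the four scored chromosomes. Positions are
# cumulative inter-marker physical distances (end of one marker gene to the
# start of the next), anchored at 0 for the first marker of each chromosome.
chromosome	marker	position_kb
III	HIS4	0
III	LEU2	23
III	CEN3	45
III	MAT	135
VII	LYS5	0
VII	MET13	56
VII	CYH2	92
VII	TRP5	227
VIII	CEN8	0
VIII	THR1	54
VIII	CUP1	106
XV	URA3	0
XV	LEU2	136
XV	LYS2	179
XV	ADE2	238
XV	HIS3	395
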