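mid_id	role	sequence
MID1	fwd	AACCACTCTG
MID2	fwd	ACTGGCCGAA
MID3	fwd	GGCAACGACA
MID4	fwd	TGTGCGGCGA
MID5	fwd	AGTGACGCTT
MID6	fwd	TCGCCGTTGC
MID7	rev	TTGAAGGAGT
MID8	rev	CTAGCAGCCG
MID9	rev	CAGTAAGGCA
MID10	rev	CAATACCTCG
MID11	rev	CTTCAATGTT
MID12	rev	TCTCGTCATA
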