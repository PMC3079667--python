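region	region_size_bp	amplicon	insert_length_bp	n_snps	cov_mean	cov_sd	multiallelic	transitions	transversions	indels
DLOOPB	423	1	381	21	25.4	10.3	1	11	8	2
ND1	1161	2	384	15	28.0	16.3	1	13	2	0
ND1	1161	3	369	5	28.2	12.3	0	5	0	0
ND1	1161	4	324	8	13.9	5.8	0	8	0	0
ND2	770	5	361	13	34.1	11.7	0	13	0	0
ND2	770	6	346	7	29.1	17.1	0	5	2	0
COXI	821	7	372	12	21.2	11.6	0	12	0	0
COXI	821	8	382	12	40.9	14.2	0	11	1	0
COXII	715	9	361	7	48.0	19.3	0	7	0	0
COXII	715	10	311	7	17.3	7.6	0	7	0	0
ATP6	414	11	375	13	35.9	14.1	0	11	2	0
ND3	403	12	357	10	30.5	12.8	0	9	1	0
ND4	1181	13	363	12	27.6	11.6	0	12	0	0
ND4	1181	14	361	13	26.7	12.5	0	13	0	0
ND4	1181	15	370	13	19.3	9.8	0	12	1	0
ND5	783	16	345	8	21.3	8.4	0	8	0	0
ND5	783	17	370	12	20.5	8.5	0	12	0	0
CYTB	1161	18	366	10	35.9	14.6	0	10	0	0
CYTB	1161	19	352	8	14.5	6.2	0	8	0	0
CYTB	1161	20	365	12	25.6	9.9	1	9	3	0
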