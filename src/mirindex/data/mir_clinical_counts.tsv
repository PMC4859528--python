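mir	variable	under_low	under_high	over_low	over_high	reported_p
miR-9	tumor_size	21	6	10	11	0.038
miR-9	tnm	26	1	12	11	<0.001
miR-18b	tumor_size	18	5	13	12	0.075
miR-18b	tnm	19	5	19	7	0.75
miR-33b	tumor_size	21	5	10	12	0.016
miR-33b	tnm	23	4	15	8	0.18
miR-106a	tumor_size	19	6	12	11	0.13
miR-106a	tnm	20	5	18	7	0.74
miR-106b	tumor_size	16	6	15	11	0.37
miR-106b	tnm	21	2	17	10	0.02
miR-210	tumor_size	20	4	11	13	0.015
miR-210	tnm	19	5	19	7	0.75
miR-372	tumor_size	8	13	23	4	<0.001
miR-372	tnm	15	8	23	4	0.18
miR-518a-3p	tumor_size	15	8	16	9	1.0
miR-518a-3p	tnm	23	1	15	11	0.002
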