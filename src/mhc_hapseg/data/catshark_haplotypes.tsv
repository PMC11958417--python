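haplotype	group	family	origin	offspring	alleles	nucl_p	aa_p	func_dist
H1	1	1	mother_g1	12	17:B,71:B	0.143	0.238	15.39
H2	1	1	mother_g1	7	31:A,50:C	0.298	0.418	28.49
H3	1	1	father*	5	21:B,70:B	0.164	0.338	21.26
H4	1	1	father*	6	51:C,65:B	0.324	0.481	36.43
H5	2	2	mother1	5	42:B,45:C	0.366	0.544	36.32
H6	2	2	mother1	6	03:A,21:B	0.193	0.350	23.68
H7	2	4	mother3	6	18:B,33:B	0.107	0.213	16.25
H8	2	4	mother3	5	72:B	NA	NA	NA
H9	2	5	mother4	4	11:A,17:B	0.168	0.288	18.74
H10	2	5	mother4	9	06:A,55:C	0.336	0.519	37.13
H11	2	2;4;5	father1	14	35:B,41:B	0.127	0.238	17.59
H12	2	2;3;4;5	father1	9	03:A,16:B	0.193	0.350	23.01
H13	2	2;5	father3	5	68:B,69:B	0.135	0.225	17.19
H14	2	5	father3	3	45:C,67:B	0.311	0.456	28.90
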