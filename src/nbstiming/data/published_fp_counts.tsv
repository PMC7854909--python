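disease	marker	direction	d_early	d_late	fp_early	fp_standard	fp_late
CTD	C0	decreased	0.23	-0.015	44	381	46
PA	C3	elevated	0.23	-0.11	29	65	4
MMA	C3	elevated	0.23	-0.11	66	97	27
IVA	C5	elevated	0.24	0.31	12	16	1
VLCADD	C14:1	elevated	-0.04	-0.26	20	97	15
CITR	Cit	elevated	0.06	-0.28	19	68	10
OTCD	Cit	decreased	0.06	-0.28	27	129	89
HCY	Met	elevated	0.50	-0.34	3	9	0
PKU	Phe	elevated	0.55	-0.41	51	112	0
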