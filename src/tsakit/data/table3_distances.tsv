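no	ligand_atom	partner	SGlu	SArg	SPhe	SLeu	note
1	O16	ARG 129[NH2]	3.59	3.75	3.61	3.64
2	O15	ARG 129[NH2]	3.54	3.51	3.69	3.35
3	O21	ARG 129[NH1]	2.66	2.78	2.62	2.68
4	O21	ARG 129[NH2]	3.16	3.18	3.28	3.29
5	O15	ASN 146[ND2]	2.91	2.92	3.04	3.01
6	O15	ARG 147[NH1]	2.80	2.80	2.94	2.81
7	O16	ARG 147[NH2]	2.93	2.82	2.76	2.83
8	N19	THR 205[O]	3.12	3.13	2.96	2.97
9	N17	TYR 255[OH]	3.08	3.14	3.13	3.09
10	O16	TYR 255[OH]	2.68	2.71	2.66	2.64	SLeu distance measured to O15
11	N19	GLU 277[OE1]	3.21	3.26	3.30	3.21
12	N17	GLU 277[OE2]	2.71	2.71	3.10	2.90
13	O20	GLU 277[OE1]	4.03	4.08	4.57	4.46
14	S18	Zn2+	3.20	3.18	3.10	3.08
15	O20	Zn2+	4.20	4.28	4.10	4.04
16	O21	Zn2+	3.21	3.31	3.10	3.02
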