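symbol	description	allele_freq	base_change	aa_change
GRM3	glutamate receptor, metabotropic 3	1.00	G/T	E/stop
BHMT2	betaine-homocysteine S-methyltransferase 2	0.29	G/T	E/stop
REXO1L1P	REX1, RNA exonuclease 1 homolog-like 1	0.24	G/A	Q/stop
FCGR1A	Fc fragment of IgG Ia, receptor (CD64)	0.22	C/T	Q/stop
ANKRD20A4	ankyrin repeat domain 20 A4	0.70	A/G	S/G
ANKRD20A1	ankyrin repeat domain 20 A1	0.69	T/C	S/P
DMBT1	deleted in malignant brain tumors 1	0.69	A/G	H/R
ANKRD20A3	ankyrin repeat domain 20 A3	0.66	A/G	S/P
ANKRD20A3	ankyrin repeat domain 20 A3	0.62	C/A	S/I
ANKRD20A1	ankyrin repeat domain 20 A1	0.58	T/C	M/T
ANKRD20A1	ankyrin repeat domain 20 A1	0.55	A/G	S/G
ANKRD20A4	ankyrin repeat domain 20 A4	0.55	C/T	R/C
GGT2	gamma-glutamyltransferase 2	0.53	C/T	A/T
PLA2G2E	phospholipase A2, group IIE	0.51	G/A	R/C
LRRC37A2	leucine rich repeat containing 37, member A2	0.51	T/G	L/V
ZNF705D	zinc finger protein 705D	0.48	G/A	G/R
NUTM2D	NUT family member 2D	0.47	T/C	W/R
RASIP1	Ras interacting protein 1	0.47	C/G	A/P
SPATA31A6	SPATA31 subfamily A, member 6	0.46	C/T	A/T
KRTAP4–12	keratin associated protein 4–12	0.46	G/C	S/R
TAF4	TAF4 RNA polymerase II	0.46	C/A	A/S
CTAGE4	CTAGE 4	0.46	A/G	I/V
NPIPA5	nuclear pore complex interacting protein A5	0.45	A/G	V/A
USH2A	Usher syndrome 2 A	0.43	C/G	V/L
PLCB2	phospholipase C, beta 2	0.42	C/T	M/I
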