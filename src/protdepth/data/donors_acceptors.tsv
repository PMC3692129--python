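res_type	atom	role	antecedent
*	N	D	CA
*	O	A	C
SER	OG	DA	CB
THR	OG1	DA	CB
TYR	OH	DA	CZ
CYS	SG	DA	CB
MET	SD	A	CG
ASN	OD1	A	CG
ASN	ND2	D	CG
GLN	OE1	A	CD
GLN	NE2	D	CD
ASP	OD1	A	CG
ASP	OD2	A	CG
GLU	OE1	A	CD
GLU	OE2	A	CD
HIS	ND1	D	CG
HIS	NE2	D	CD2
LYS	NZ	D	CE
ARG	NE	D	CD
ARG	NH1	D	CZ
ARG	NH2	D	CZ
TRP	NE1	D	CD1
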