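res_type	atom
SER	OG
THR	OG1
TYR	OH
ASN	OD1
ASN	ND2
GLN	OE1
GLN	NE2
ASP	OD1
ASP	OD2
GLU	OE1
GLU	OE2
HIS	ND1
HIS	NE2
LYS	NZ
ARG	NE
ARG	NH1
ARG	NH2
TRP	NE1
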