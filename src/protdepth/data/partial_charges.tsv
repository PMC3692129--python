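res_type	atom	charge
*	N	-0.31
*	CA	0.31
*	C	0.45
*	O	-0.45
ASP	CG	0.27
ASP	OD1	-0.635
ASP	OD2	-0.635
GLU	CD	0.27
GLU	OE1	-0.635
GLU	OE2	-0.635
LYS	CE	0.127
LYS	NZ	0.873
ARG	CZ	0.34
ARG	NH1	0.33
ARG	NH2	0.33
HIS	ND1	0.5
HIS	NE2	0.5
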