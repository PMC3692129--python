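res_type	model_pka	c0	c1	c2	c3	c4	c5
ASP	3.8	-2.18	0.29	0.47	-0.61	0.16	-0.15
GLU	4.5	-1.91	-0.1	0.79	-0.19	0.26	-0.09
HIS	6.5	3.13	-0.04	-0.54	0.28	-1.12	-0.83
LYS	10.5	4.22	-0.21	-0.19	-0.01	-7.65	-1.81
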