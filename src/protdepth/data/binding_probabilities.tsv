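res_type	d_lo	d_hi	s_lo	s_hi	p
ALA	0	2.0	0	25	0.0362
ALA	0	2.0	25	50	0.0488
ALA	0	2.0	50	75	0.0612
ALA	0	2.0	75	100	0.0737
ALA	2	4.0	0	25	0.0488
ALA	2	4.0	25	50	0.0862
ALA	2	4.0	50	75	0.1237
ALA	2	4.0	75	100	0.1613
ALA	4	6.0	0	25	0.0612
ALA	4	6.0	25	50	0.1237
ALA	4	6.0	50	75	0.1862
ALA	4	6.0	75	100	0.2487
ALA	6	inf	0	25	0.0737
ALA	6	inf	25	50	0.1612
ALA	6	inf	50	75	0.2487
ALA	6	inf	75	100	0.3362
ARG	0	2.0	0	25	0.0407
ARG	0	2.0	25	50	0.0621
ARG	0	2.0	50	75	0.0836
ARG	0	2.0	75	100	0.105
ARG	2	4.0	0	25	0.0621
ARG	2	4.0	25	50	0.1264
ARG	2	4.0	50	75	0.1907
ARG	2	4.0	75	100	0.255
ARG	4	6.0	0	25	0.0836
ARG	4	6.0	25	50	0.1907
ARG	4	6.0	50	75	0.2979
ARG	4	6.0	75	100	0.405
ARG	6	inf	0	25	0.105
ARG	6	inf	25	50	0.255
ARG	6	inf	50	75	0.405
ARG	6	inf	75	100	0.555
ASN	0	2.0	0	25	0.0389
ASN	0	2.0	25	50	0.0568
ASN	0	2.0	50	75	0.0746
ASN	0	2.0	75	100	0.0925
ASN	2	4.0	0	25	0.0568
ASN	2	4.0	25	50	0.1104
ASN	2	4.0	50	75	0.1639
ASN	2	4.0	75	100	0.2175
ASN	4	6.0	0	25	0.0746
ASN	4	6.0	25	50	0.1639
ASN	4	6.0	50	75	0.2532
ASN	4	6.0	75	100	0.3425
ASN	6	inf	0	25	0.0925
ASN	6	inf	25	50	0.2175
ASN	6	inf	50	75	0.3425
ASN	6	inf	75	100	0.4675
ASP	0	2.0	0	25	0.0403
ASP	0	2.0	25	50	0.0608
ASP	0	2.0	50	75	0.0813
ASP	0	2.0	75	100	0.1019
ASP	2	4.0	0	25	0.0608
ASP	2	4.0	25	50	0.1224
ASP	2	4.0	50	75	0.184
ASP	2	4.0	75	100	0.2456
ASP	4	6.0	0	25	0.0813
ASP	4	6.0	25	50	0.184
ASP	4	6.0	50	75	0.2867
ASP	4	6.0	75	100	0.3894
ASP	6	inf	0	25	0.1019
ASP	6	inf	25	50	0.2456
ASP	6	inf	50	75	0.3894
ASP	6	inf	75	100	0.5331
CYS	0	2.0	0	25	0.0389
CYS	0	2.0	25	50	0.0568
CYS	0	2.0	50	75	0.0746
CYS	0	2.0	75	100	0.0925
CYS	2	4.0	0	25	0.0568
CYS	2	4.0	25	50	0.1104
CYS	2	4.0	50	75	0.1639
CYS	2	4.0	75	100	0.2175
CYS	4	6.0	0	25	0.0746
CYS	4	6.0	25	50	0.1639
CYS	4	6.0	50	75	0.2532
CYS	4	6.0	75	100	0.3425
CYS	6	inf	0	25	0.0925
CYS	6	inf	25	50	0.2175
CYS	6	inf	50	75	0.3425
CYS	6	inf	75	100	0.4675
GLN	0	2.0	0	25	0.0389
GLN	0	2.0	25	50	0.0568
GLN	0	2.0	50	75	0.0746
GLN	0	2.0	75	100	0.0925
GLN	2	4.0	0	25	0.0568
GLN	2	4.0	25	50	0.1104
GLN	2	4.0	50	75	0.1639
GLN	2	4.0	75	100	0.2175
GLN	4	6.0	0	25	0.0746
GLN	4	6.0	25	50	0.1639
GLN	4	6.0	50	75	0.2532
GLN	4	6.0	75	100	0.3425
GLN	6	inf	0	25	0.0925
GLN	6	inf	25	50	0.2175
GLN	6	inf	50	75	0.3425
GLN	6	inf	75	100	0.4675
GLU	0	2.0	0	25	0.0398
GLU	0	2.0	25	50	0.0595
GLU	0	2.0	50	75	0.0791
GLU	0	2.0	75	100	0.0988
GLU	2	4.0	0	25	0.0595
GLU	2	4.0	25	50	0.1184
GLU	2	4.0	50	75	0.1773
GLU	2	4.0	75	100	0.2362
GLU	4	6.0	0	25	0.0791
GLU	4	6.0	25	50	0.1773
GLU	4	6.0	50	75	0.2755
GLU	4	6.0	75	100	0.3738
GLU	6	inf	0	25	0.0988
GLU	6	inf	25	50	0.2363
GLU	6	inf	50	75	0.3738
GLU	6	inf	75	100	0.5113
GLY	0	2.0	0	25	0.0371
GLY	0	2.0	25	50	0.0514
GLY	0	2.0	50	75	0.0657
GLY	0	2.0	75	100	0.08
GLY	2	4.0	0	25	0.0514
GLY	2	4.0	25	50	0.0943
GLY	2	4.0	50	75	0.1371
GLY	2	4.0	75	100	0.18
GLY	4	6.0	0	25	0.0657
GLY	4	6.0	25	50	0.1371
GLY	4	6.0	50	75	0.2086
GLY	4	6.0	75	100	0.28
GLY	6	inf	0	25	0.08
GLY	6	inf	25	50	0.18
GLY	6	inf	50	75	0.28
GLY	6	inf	75	100	0.38
HIS	0	2.0	0	25	0.0434
HIS	0	2.0	25	50	0.0702
HIS	0	2.0	50	75	0.097
HIS	0	2.0	75	100	0.1237
HIS	2	4.0	0	25	0.0702
HIS	2	4.0	25	50	0.1505
HIS	2	4.0	50	75	0.2309
HIS	2	4.0	75	100	0.3113
HIS	4	6.0	0	25	0.097
HIS	4	6.0	25	50	0.2309
HIS	4	6.0	50	75	0.3648
HIS	4	6.0	75	100	0.4988
HIS	6	inf	0	25	0.1237
HIS	6	inf	25	50	0.3113
HIS	6	inf	50	75	0.4988
HIS	6	inf	75	100	0.6863
ILE	0	2.0	0	25	0.0371
ILE	0	2.0	25	50	0.0514
ILE	0	2.0	50	75	0.0657
ILE	0	2.0	75	100	0.08
ILE	2	4.0	0	25	0.0514
ILE	2	4.0	25	50	0.0943
ILE	2	4.0	50	75	0.1371
ILE	2	4.0	75	100	0.18
ILE	4	6.0	0	25	0.0657
ILE	4	6.0	25	50	0.1371
ILE	4	6.0	50	75	0.2086
ILE	4	6.0	75	100	0.28
ILE	6	inf	0	25	0.08
ILE	6	inf	25	50	0.18
ILE	6	inf	50	75	0.28
ILE	6	inf	75	100	0.38
LEU	0	2.0	0	25	0.0371
LEU	0	2.0	25	50	0.0514
LEU	0	2.0	50	75	0.0657
LEU	0	2.0	75	100	0.08
LEU	2	4.0	0	25	0.0514
LEU	2	4.0	25	50	0.0943
LEU	2	4.0	50	75	0.1371
LEU	2	4.0	75	100	0.18
LEU	4	6.0	0	25	0.0657
LEU	4	6.0	25	50	0.1371
LEU	4	6.0	50	75	0.2086
LEU	4	6.0	75	100	0.28
LEU	6	inf	0	25	0.08
LEU	6	inf	25	50	0.18
LEU	6	inf	50	75	0.28
LEU	6	inf	75	100	0.38
LYS	0	2.0	0	25	0.038
LYS	0	2.0	25	50	0.0541
LYS	0	2.0	50	75	0.0702
LYS	0	2.0	75	100	0.0862
LYS	2	4.0	0	25	0.0541
LYS	2	4.0	25	50	0.1023
LYS	2	4.0	50	75	0.1505
LYS	2	4.0	75	100	0.1987
LYS	4	6.0	0	25	0.0702
LYS	4	6.0	25	50	0.1505
LYS	4	6.0	50	75	0.2309
LYS	4	6.0	75	100	0.3113
LYS	6	inf	0	25	0.0862
LYS	6	inf	25	50	0.1988
LYS	6	inf	50	75	0.3113
LYS	6	inf	75	100	0.4237
MET	0	2.0	0	25	0.0389
MET	0	2.0	25	50	0.0568
MET	0	2.0	50	75	0.0746
MET	0	2.0	75	100	0.0925
MET	2	4.0	0	25	0.0568
MET	2	4.0	25	50	0.1104
MET	2	4.0	50	75	0.1639
MET	2	4.0	75	100	0.2175
MET	4	6.0	0	25	0.0746
MET	4	6.0	25	50	0.1639
MET	4	6.0	50	75	0.2532
MET	4	6.0	75	100	0.3425
MET	6	inf	0	25	0.0925
MET	6	inf	25	50	0.2175
MET	6	inf	50	75	0.3425
MET	6	inf	75	100	0.4675
PHE	0	2.0	0	25	0.0407
PHE	0	2.0	25	50	0.0621
PHE	0	2.0	50	75	0.0836
PHE	0	2.0	75	100	0.105
PHE	2	4.0	0	25	0.0621
PHE	2	4.0	25	50	0.1264
PHE	2	4.0	50	75	0.1907
PHE	2	4.0	75	100	0.255
PHE	4	6.0	0	25	0.0836
PHE	4	6.0	25	50	0.1907
PHE	4	6.0	50	75	0.2979
PHE	4	6.0	75	100	0.405
PHE	6	inf	0	25	0.105
PHE	6	inf	25	50	0.255
PHE	6	inf	50	75	0.405
PHE	6	inf	75	100	0.555
PRO	0	2.0	0	25	0.0362
PRO	0	2.0	25	50	0.0488
PRO	0	2.0	50	75	0.0612
PRO	0	2.0	75	100	0.0737
PRO	2	4.0	0	25	0.0488
PRO	2	4.0	25	50	0.0862
PRO	2	4.0	50	75	0.1237
PRO	2	4.0	75	100	0.1613
PRO	4	6.0	0	25	0.0612
PRO	4	6.0	25	50	0.1237
PRO	4	6.0	50	75	0.1862
PRO	4	6.0	75	100	0.2487
PRO	6	inf	0	25	0.0737
PRO	6	inf	25	50	0.1612
PRO	6	inf	50	75	0.2487
PRO	6	inf	75	100	0.3362
SER	0	2.0	0	25	0.0389
SER	0	2.0	25	50	0.0568
SER	0	2.0	50	75	0.0746
SER	0	2.0	75	100	0.0925
SER	2	4.0	0	25	0.0568
SER	2	4.0	25	50	0.1104
SER	2	4.0	50	75	0.1639
SER	2	4.0	75	100	0.2175
SER	4	6.0	0	25	0.0746
SER	4	6.0	25	50	0.1639
SER	4	6.0	50	75	0.2532
SER	4	6.0	75	100	0.3425
SER	6	inf	0	25	0.0925
SER	6	inf	25	50	0.2175
SER	6	inf	50	75	0.3425
SER	6	inf	75	100	0.4675
THR	0	2.0	0	25	0.0389
THR	0	2.0	25	50	0.0568
THR	0	2.0	50	75	0.0746
THR	0	2.0	75	100	0.0925
THR	2	4.0	0	25	0.0568
THR	2	4.0	25	50	0.1104
THR	2	4.0	50	75	0.1639
THR	2	4.0	75	100	0.2175
THR	4	6.0	0	25	0.0746
THR	4	6.0	25	50	0.1639
THR	4	6.0	50	75	0.2532
THR	4	6.0	75	100	0.3425
THR	6	inf	0	25	0.0925
THR	6	inf	25	50	0.2175
THR	6	inf	50	75	0.3425
THR	6	inf	75	100	0.4675
TRP	0	2.0	0	25	0.0425
TRP	0	2.0	25	50	0.0675
TRP	0	2.0	50	75	0.0925
TRP	0	2.0	75	100	0.1175
TRP	2	4.0	0	25	0.0675
TRP	2	4.0	25	50	0.1425
TRP	2	4.0	50	75	0.2175
TRP	2	4.0	75	100	0.2925
TRP	4	6.0	0	25	0.0925
TRP	4	6.0	25	50	0.2175
TRP	4	6.0	50	75	0.3425
TRP	4	6.0	75	100	0.4675
TRP	6	inf	0	25	0.1175
TRP	6	inf	25	50	0.2925
TRP	6	inf	50	75	0.4675
TRP	6	inf	75	100	0.6425
TYR	0	2.0	0	25	0.0416
TYR	0	2.0	25	50	0.0648
TYR	0	2.0	50	75	0.088
TYR	0	2.0	75	100	0.1113
TYR	2	4.0	0	25	0.0648
TYR	2	4.0	25	50	0.1345
TYR	2	4.0	50	75	0.2041
TYR	2	4.0	75	100	0.2738
TYR	4	6.0	0	25	0.088
TYR	4	6.0	25	50	0.2041
TYR	4	6.0	50	75	0.3202
TYR	4	6.0	75	100	0.4363
TYR	6	inf	0	25	0.1113
TYR	6	inf	25	50	0.2738
TYR	6	inf	50	75	0.4363
TYR	6	inf	75	100	0.5988
VAL	0	2.0	0	25	0.0371
VAL	0	2.0	25	50	0.0514
VAL	0	2.0	50	75	0.0657
VAL	0	2.0	75	100	0.08
VAL	2	4.0	0	25	0.0514
VAL	2	4.0	25	50	0.0943
VAL	2	4.0	50	75	0.1371
VAL	2	4.0	75	100	0.18
VAL	4	6.0	0	25	0.0657
VAL	4	6.0	25	50	0.1371
VAL	4	6.0	50	75	0.2086
VAL	4	6.0	75	100	0.28
VAL	6	inf	0	25	0.08
VAL	6	inf	25	50	0.18
VAL	6	inf	50	75	0.28
VAL	6	inf	75	100	0.38
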