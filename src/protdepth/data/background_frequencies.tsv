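aa	frequency
A	0.074
R	0.052
N	0.045
D	0.054
C	0.025
Q	0.034
E	0.054
G	0.074
H	0.026
I	0.068
L	0.099
K	0.058
M	0.025
F	0.047
P	0.039
S	0.057
T	0.051
W	0.013
Y	0.032
V	0.073
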