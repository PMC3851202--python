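residue	fraction
A	0.079
R	0.054
N	0.043
D	0.054
C	0.017
Q	0.039
E	0.065
G	0.067
H	0.023
I	0.053
L	0.092
K	0.059
M	0.024
F	0.040
P	0.049
S	0.081
T	0.053
V	0.064
W	0.012
Y	0.032
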