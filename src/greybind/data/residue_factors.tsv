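residue	factor_score
A	-0.733
C	-0.862
D	-3.656
E	1.477
F	1.891
G	1.330
H	-1.673
I	2.131
K	0.533
L	-1.505
M	2.219
N	1.299
P	-1.628
Q	-3.005
R	1.502
S	-4.760
T	2.213
V	-0.544
W	0.672
Y	3.097
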