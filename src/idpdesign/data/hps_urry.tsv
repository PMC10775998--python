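residue	lambda	sigma	charge	mass
A	0.602942	5.04	0.0	71.0788
C	0.647060	5.48	0.0	103.1388
D	0.294118	5.58	-1.0	115.0886
E	0.000000	5.92	-1.0	129.1155
F	0.823530	6.36	0.0	147.1766
G	0.573530	4.50	0.0	57.0519
H	0.764706	6.08	0.0	137.1411
I	0.705882	6.18	0.0	113.1594
K	0.382353	6.36	1.0	128.1741
L	0.720588	6.18	0.0	113.1594
M	0.838235	6.18	0.0	131.1926
N	0.588236	5.68	0.0	114.1038
P	0.758824	5.56	0.0	97.1167
Q	0.558824	6.02	0.0	128.1307
R	0.558824	6.56	1.0	156.1875
S	0.588236	5.18	0.0	87.0782
T	0.588236	5.62	0.0	101.1051
V	0.664706	5.86	0.0	99.1326
W	1.000000	6.78	0.0	186.2132
Y	0.897059	6.46	0.0	163.1760
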