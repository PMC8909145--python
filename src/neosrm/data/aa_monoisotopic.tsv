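# Monoisotopic residue masses (Da) for the 20 standard amino acids,
# computed from CODATA/IUPAC 2021 isotope masses of the residue formulas.
# version: 1.0
A	71.037114
C	103.009185
D	115.026943
E	129.042593
F	147.068414
G	57.021464
H	137.058912
I	113.084064
K	128.094963
L	113.084064
M	131.040485
N	114.042927
P	97.052764
Q	128.058578
R	156.101111
S	87.032028
T	101.047678
V	99.068414
W	186.079313
Y	163.063329
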