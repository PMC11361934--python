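# Average residue masses (Da); peptide mass = sum + 18.0153 (water).
# Transcribed from the descriptor literature; see docs/methods.md for provenance.
residue,value
A,71.0788
C,103.139
D,115.089
E,129.115
F,147.177
G,57.0519
H,137.141
I,113.159
K,128.174
L,113.159
M,131.193
N,114.104
P,97.1167
Q,128.131
R,156.188
S,87.0782
T,101.105
V,99.1326
W,186.213
Y,163.176
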