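# Physical descriptors PD1 (volume), PD2 (hydrophilicity).
# SYNTHETIC stand-in: seeded mixture of measured residue properties preserving the family's documented dimensionality and semantics; not the original published values. See docs/methods.md.
residue,PD1,PD2
A,-1.31,-0.79
C,-0.81,-1.03
D,-0.75,1.03
E,-0.07,1.03
F,1.21,-1.13
G,-2.01,-0.03
H,0.3,0.93
I,0.63,-1.71
K,0.68,1.17
L,0.63,-1.47
M,0.54,-0.82
N,-0.67,1.03
P,-0.71,0.38
Q,0.06,1.03
R,0.8,1.38
S,-1.3,0.11
T,-0.62,0.07
V,-0.03,-1.61
W,2.14,0.14
Y,1.3,0.28
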