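# T-scales T1-T5 (topological descriptors).
# SYNTHETIC stand-in: seeded mixture of measured residue properties preserving the family's documented dimensionality and semantics; not the original published values. See docs/methods.md.
residue,T1,T2,T3,T4,T5
A,-1.25,-0.46,-0.3,-0.48,-0.11
C,-0.95,-0.35,-0.23,-0.25,-0.6
D,2.48,0.28,0.31,-0.93,0.25
E,2.39,0.37,0.17,-0.39,0.06
F,-1.3,-1.11,2.11,1.62,-1.74
G,-0.75,-1.69,-0.31,-1.98,1.42
H,0.03,0.56,1.04,0.93,-0.97
I,0.29,1.38,-1.12,-0.21,0.23
K,-0.74,-0.14,-0.87,0.83,1.39
L,-0.04,2.05,-1.13,0.15,-0.51
M,-0.87,0.33,-0.44,1.09,-1.12
N,0.8,0.19,-0.12,-0.48,0.56
P,-0.44,-1.11,-0.46,-0.95,0.86
Q,0.68,-0.1,-0.33,-0.12,0.65
R,0.18,-0.23,-0.68,0.49,1.56
S,-0.13,-1.03,-0.23,-1.27,0.99
T,0.4,0.92,-0.56,-0.81,0.29
V,0.16,1.91,-0.96,-0.38,-0.21
W,-0.55,-0.41,2.04,2.15,-2.03
Y,-0.42,-1.34,2.08,0.98,-0.98
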