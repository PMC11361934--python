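# Sneath vectors SV1-SV4 (PCA of binary residue traits).
# SYNTHETIC stand-in: seeded mixture of measured residue properties preserving the family's documented dimensionality and semantics; not the original published values. See docs/methods.md.
residue,SV1,SV2,SV3,SV4
A,-0.86,-0.47,0.29,-1.02
C,-0.61,-1.02,0.73,-1.22
D,-0.85,1.62,-1.92,2.13
E,-0.42,1.45,-1.77,2.02
F,2,-0.63,0.92,-0.42
G,-1.38,0.21,-0.72,0.84
H,0.46,0.71,-0.56,-0.86
I,0.34,-1.52,1.69,0.02
K,0.11,0.95,0.18,-0.35
L,0.29,-1.79,1.57,-1.19
M,0.22,-0.99,0.94,-1.62
N,-0.8,1.07,-0.91,0.41
P,-0.66,0.06,-0.65,0.5
Q,-0.32,0.88,-0.81,0.69
R,0.06,1.08,0.15,0.38
S,-1.01,0.35,-0.5,0.72
T,-0.67,-0.22,-0.09,-0.26
V,-0.11,-1.52,1.53,-0.85
W,2.36,-0.3,0.2,-0.56
Y,1.84,0.09,-0.27,0.63
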