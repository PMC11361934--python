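# ProtFP descriptors 1-8 (PCA of AAindex entries).
# SYNTHETIC stand-in: seeded mixture of measured residue properties preserving the family's documented dimensionality and semantics; not the original published values. See docs/methods.md.
residue,ProtFP1,ProtFP2,ProtFP3,ProtFP4,ProtFP5,ProtFP6,ProtFP7,ProtFP8
A,1.1,-1.69,-0.2,0.13,-0.43,-0.17,-0.92,0.59
C,1.57,-1.44,-0.06,-1.22,-0.78,-0.33,0.07,0.84
D,-1.68,-0.36,-2.37,1.61,1.16,0.66,-1.12,-1.17
E,-1.69,0.3,-2.34,1.16,0.9,0.41,-0.67,-1.32
F,1.08,-0.79,0.16,-1.02,-1.08,1.53,1.43,0.31
G,-0.11,-1.25,-0.54,1.49,1.93,0.22,-1.93,-0.11
H,-0.43,-0.67,0.25,0.04,-1.51,-0.08,0.5,-0.61
I,0.94,2.03,0.82,-0.62,0.49,0.98,0.45,1.85
K,-0.78,0.49,1.62,0.76,-0.05,-2.22,-0.17,-0.76
L,1.17,1.97,0.99,-1.21,-0.73,0.7,0.76,1.83
M,1.38,-0.37,0.04,-1.79,-1.72,-0.91,0.89,0.48
N,-0.87,-0.62,-0.3,0.92,0.24,-0.64,-0.7,-0.66
P,-0.35,-0.02,-0.41,0.43,1.13,-0.4,-0.8,-0.54
Q,-1.02,0.31,-0.34,0.58,0.51,-0.82,-0.33,-0.93
R,-0.99,0.61,1.62,0.33,0.48,-2.21,0.29,-0.8
S,-0.16,-0.98,-0.42,0.92,1.27,-0.1,-1.19,-0.15
T,-0.08,0.42,0.29,0.23,0.14,0.19,-0.39,0.47
V,1.2,1.21,0.93,-0.61,-0.32,1.02,0.25,2.07
W,0.11,0.56,0.25,-1.63,-1.61,0.85,2.27,-0.62
Y,-0.38,0.3,0.01,-0.5,0,1.32,1.31,-0.77
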