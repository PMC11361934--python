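# PCP descriptors 1-5 (multidimensional scaling of physicochemical properties).
# SYNTHETIC stand-in: seeded mixture of measured residue properties preserving the family's documented dimensionality and semantics; not the original published values. See docs/methods.md.
residue,PCP1,PCP2,PCP3,PCP4,PCP5
A,-0.53,-1.51,-0.18,0.18,-0.54
C,0.17,-0.68,-0.84,0.57,-0.09
D,-0.99,-0.63,1.79,-2.13,0.37
E,-0.61,0.01,1.54,-1.98,0.44
F,1.2,0.86,-1.93,1.21,-0.06
G,-1.06,-2.15,0.37,-0.74,1.42
H,-0.84,0.48,0.2,-0.04,-1.56
I,2.04,0.41,-0.48,1.22,-0.48
K,-0.87,0.39,0.74,0.05,0.56
L,1.75,0.64,-0.62,1.45,-1.87
M,0.63,0.54,-0.92,0.76,-0.63
N,-1.2,-0.51,1.16,-0.93,0.01
P,-0.55,-0.66,0.08,-0.57,1.24
Q,-0.69,0.15,0.83,-0.86,0.68
R,-0.61,0.84,0.73,-0.11,1.57
S,-0.76,-1.33,0.43,-0.65,1.17
T,-0.19,-0.39,0.47,0.01,-0.89
V,1.45,-0.07,-0.29,1.28,-1.74
W,1.01,2.27,-1.72,0.91,-0.4
Y,0.62,1.33,-1.34,0.38,0.82
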