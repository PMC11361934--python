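# BLOSUM indices 1-10 (VARIMAX components of BLOSUM62).
# SYNTHETIC stand-in: seeded mixture of measured residue properties preserving the family's documented dimensionality and semantics; not the original published values. See docs/methods.md.
residue,BLOSUM1,BLOSUM2,BLOSUM3,BLOSUM4,BLOSUM5,BLOSUM6,BLOSUM7,BLOSUM8,BLOSUM9,BLOSUM10
A,0.78,-0.47,-0.78,-0.32,-0.72,-1.37,-1.54,0.11,0.28,-0.41
C,0.68,-0.47,-1.62,-0.5,-1.48,-1.29,-1.01,0.54,-1.13,-0.1
D,-0.28,1.21,1.64,-0.34,0.46,1.4,0.35,-0.74,2.03,0.07
E,-0.68,1.86,1.63,-0.32,0.28,1.64,0.75,-0.6,1.53,0.54
F,1.15,1.29,-0.91,-1.13,1.21,-1.13,0.38,1.84,-1.3,1.67
G,0.7,-1.63,-0.18,0.13,0.02,-0.27,-1.88,-0.42,0.32,-1.75
H,-0.69,0.44,0.57,0.33,1.34,-0.22,0.68,-0.68,0.97,1.01
I,1.55,-0.6,-0.79,-1.09,-1.25,-0.54,-0.4,1.54,-0.48,-0.53
K,-1.82,-0.22,1.42,2.34,0.56,1.12,1.22,-1.52,0.47,-0.59
L,1.16,-0.57,-1.16,-1.2,-1.35,-1.13,-0.63,1.22,-0.4,0.04
M,-0.23,1.06,-1.16,-0.31,-1.56,-0.8,0.05,0.53,-1.29,1
N,-0.73,-0.28,0.98,0.8,0.35,0.67,0.29,-1.19,1.24,-0.47
P,-0.39,-0.56,-0.14,0.33,-0.26,0.37,-0.77,-0.5,-0.53,-0.75
Q,-1.14,0.33,0.97,0.86,0.17,1.18,0.66,-0.98,0.41,-0.18
R,-1.92,-0.66,1.29,2.5,0.36,1.78,1.91,-1.49,-0.23,-0.87
S,0.28,-0.98,0.04,0.29,-0.13,0.1,-0.87,-0.42,0.24,-1.18
T,0.28,-1.16,-0.12,-0.14,-0.25,-0.3,-0.63,-0.31,0.65,-0.66
V,1.73,-1.14,-1.01,-1.21,-1.15,-1.3,-0.92,1.21,0.23,-0.51
W,-0.44,1.76,-0.49,-0.58,1.46,-0.13,1.48,1,-1.66,2.39
Y,0.02,0.79,-0.19,-0.45,1.93,0.21,0.88,0.85,-1.35,1.28
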