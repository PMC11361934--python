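# ST-scales ST1-ST8 (Yang et al. 2010).
# SYNTHETIC stand-in: seeded mixture of measured residue properties preserving the family's documented dimensionality and semantics; not the original published values. See docs/methods.md.
residue,ST1,ST2,ST3,ST4,ST5,ST6,ST7,ST8
A,-0.59,1.4,0.29,-1.7,0.18,-0.48,-0.58,-0.34
C,-0.13,1.16,-0.75,-0.51,0.56,0.06,-0.9,-0.64
D,-1.31,-1.12,1.81,-0.07,-0.96,-2.2,0.73,-0.2
E,-0.86,-1.44,1.45,0.53,-0.89,-1.98,0.52,-0.32
F,1.76,0.72,-1.49,0.55,0.39,0.6,-2.05,2.19
G,-1.7,1.28,1.05,-1.82,-0.25,-0.42,1.11,-0.59
H,0.62,-0.95,0.1,0.02,-0.87,0.1,-0.82,0.85
I,0.31,1.17,-0.73,-0.19,2.06,-0.18,0.38,0.46
K,0.35,-0.97,0.6,0.78,-1.12,1.79,0.96,-1.1
L,0.57,0.92,-1.03,-0.54,2.02,-0.27,-0.25,0.51
M,0.81,0.27,-1.09,0.52,0.45,0.27,-1.42,-0.72
N,-0.74,-0.75,1.07,-0.14,-0.93,-0.29,0.68,-0.6
P,-0.83,0.16,0.3,-0.35,-0.31,0.05,0.75,-0.89
Q,-0.38,-1.03,0.67,0.63,-0.83,0.04,0.75,-0.83
R,0.28,-1.43,0.26,1.91,-1.12,2.2,1.41,-1.38
S,-1.16,0.59,0.77,-0.8,-0.32,-0.22,0.82,-0.65
T,-0.58,0.17,0.29,-0.86,0.39,-0.4,0.58,-0.05
V,0.11,1.34,-0.55,-1.09,1.97,-0.51,0.01,0.68
W,2.19,-0.98,-1.84,1.85,-0.13,0.99,-1.87,1.82
Y,1.29,-0.53,-1.16,1.26,-0.29,0.84,-0.84,1.81
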