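# FASGAI vectors F1-F6 (Liang & Li 2007).
# SYNTHETIC stand-in: seeded mixture of measured residue properties preserving the family's documented dimensionality and semantics; not the original published values. See docs/methods.md.
residue,F1,F2,F3,F4,F5,F6
A,-0.59,1.04,-1.14,0.25,0.66,-0.18
C,0.59,-0.42,-0.49,2.6,-0.53,0.36
D,-1.29,-0.48,-0.58,-0.52,0.77,-1.74
E,-1.31,0.6,-0.11,-0.72,0.43,-1.6
F,1.59,-0.49,1.27,-0.29,-0.66,0.45
G,-1.05,-1.6,-1.96,0.3,1.57,-0.09
H,0.05,-0.24,0.56,0.26,-0.39,0.77
I,1.56,0.17,0.35,-0.53,-0.83,0.08
K,-1.17,0.74,0.45,-0.29,0.73,1.41
L,1.46,0.52,0.33,-0.44,-0.52,0.04
M,1.12,0.36,0.29,0.65,-0.58,0.2
N,-0.91,-0.86,-0.44,-0.21,0.83,-0.56
P,-0.58,-2.18,-0.6,-0.16,1.64,-0.06
Q,-0.82,0.52,0.04,-0.41,0.36,-0.38
R,-0.93,0.46,0.88,-0.29,0.38,1.96
S,-0.84,-0.74,-1,0.19,0.96,-0.25
T,-0.49,-0.55,-0.52,-0.1,0.4,-0.19
V,1.24,-0.02,-0.09,-0.46,-0.7,-0.01
W,1.82,-0.17,2.07,0.34,-1.02,0.75
Y,1.05,-0.4,1.34,-0.11,-0.74,0.59
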