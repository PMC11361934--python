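# MS-WHIM scores 1-3 (Zaliani & Gancia 1999).
# Transcribed from the descriptor literature; see docs/methods.md for provenance.
residue,MSWHIM1,MSWHIM2,MSWHIM3
A,-0.73,0.2,-0.62
C,-0.66,0.26,-0.27
D,0.11,-1,-0.96
E,0.24,-0.39,-0.04
F,0.76,0.85,-0.34
G,-0.31,-0.28,-0.75
H,0.84,0.67,-0.78
I,-0.91,0.83,-0.25
K,-0.51,0.08,0.7
L,-0.74,0.72,-0.16
M,-0.7,1,-0.32
N,0.14,0.2,-0.66
P,-0.43,0.73,-0.6
Q,0.3,1,-0.3
R,-0.22,0.27,1
S,-0.8,0.61,-1
T,-0.58,0.85,-0.89
V,-1,0.79,-0.58
W,1,0.98,-0.47
Y,0.97,0.66,-0.23
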