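# Cruciani properties PP1-PP3 (Cruciani et al. 2004).
# Transcribed from the descriptor literature; see docs/methods.md for provenance.
residue,PP1,PP2,PP3
A,-0.96,-0.76,0.31
C,-0.55,-0.47,0.19
D,0.82,-0.89,-0.94
E,0.94,-0.54,-0.99
F,-0.85,0.48,-0.58
G,-0.88,-1,0.49
H,0.67,-0.11,0.37
I,-0.94,-0.05,-0.18
K,0.6,0.1,1
L,-0.9,0.03,-0.24
M,-0.82,0.03,-0.08
N,0.82,-0.57,0.02
P,-0.81,-0.44,-0.18
Q,0.78,-0.3,-0.38
R,0.8,0.63,0.99
S,0.41,-0.97,0.37
T,0.4,-0.64,0.27
V,-0.9,-0.22,-0.15
W,-0.6,1,-0.48
Y,-0.58,0.82,-0.41
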