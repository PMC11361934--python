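# SVGER descriptors 1-11 (geometrical/eigenvalue/Randic PCA).
# SYNTHETIC stand-in: seeded mixture of measured residue properties preserving the family's documented dimensionality and semantics; not the original published values. See docs/methods.md.
residue,SVGER1,SVGER2,SVGER3,SVGER4,SVGER5,SVGER6,SVGER7,SVGER8,SVGER9,SVGER10,SVGER11
A,-1.8,-0.76,0.63,-1.72,-0.32,-0.72,-0.99,0.19,-1.37,-1.84,-0.39
C,-1.06,0.51,0.07,-1.12,-0.37,0.24,-0.25,0.43,-1.09,-1.39,-0.72
D,-0.32,-1.67,0.36,-0.35,0.05,-1.7,-0.1,-1.09,-0.79,0.06,0.78
E,0.31,-1.17,-0,0.33,-0.05,-1.28,0.17,-1.03,-0.27,0.37,0.73
F,0.83,1.27,-0.61,0.21,-1.85,1.42,1.63,0.52,1.05,-0.22,1.58
G,-1.98,-1.59,0.79,-2.25,1.27,-1.63,-1.26,-0.46,-1.9,-1.47,-0.72
H,0.08,-0.29,-0.27,0.39,-1.41,0.34,0.82,-0.42,0.66,-0.35,1.15
I,0.8,1.02,1.29,0.62,0.74,0.37,-0.84,1.87,0.67,2.03,-0.15
K,0.51,-0.07,-1.52,1.02,1.11,0.43,-0.29,-1.02,0.62,0.09,-1.56
L,0.56,1.03,1.6,0.73,-0.11,0.56,-0.75,2.09,0.87,1.63,0.29
M,0.1,1.17,-0.61,0.32,-0.9,0.95,0.22,0.41,0.03,-0.79,-0.58
N,-0.52,-0.97,-0.19,-0.27,0.33,-0.71,-0.25,-0.88,-0.55,-0.37,-0.29
P,-0.63,-0.54,0.01,-0.68,0.92,-0.66,-0.45,-0.47,-0.79,-0.69,-0.7
Q,0.26,-0.41,-0.64,0.44,0.6,-0.33,0.03,-0.89,-0.03,0.1,-0.5
R,1.13,0.6,-2.06,1.39,1.63,0.88,0.3,-1.21,0.64,0.78,-1.94
S,-1.17,-0.94,0.19,-1.34,0.95,-0.99,-0.71,-0.51,-1.32,-0.9,-0.73
T,-0.48,-0.46,1.09,-0.29,0.33,-0.5,-0.69,0.49,-0.23,0.39,0.08
V,-0.03,0.52,1.87,0.01,0.1,0.11,-1.06,2,0.31,1.39,0.25
W,2,1.78,-1.17,1.73,-2.02,2.03,2.47,0.15,2.1,0.63,1.81
Y,1.41,0.97,-0.82,0.83,-1,1.18,2,-0.16,1.37,0.55,1.58
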