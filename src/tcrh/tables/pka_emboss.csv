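# EMBOSS pKa set; sign +1 = basic (protonated below pKa), -1 = acidic.
group,pka,sign
n_term,8.6,1
c_term,3.6,-1
C,8.5,-1
D,3.9,-1
E,4.1,-1
Y,10.1,-1
H,6.5,1
K,10.8,1
R,12.5,1
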