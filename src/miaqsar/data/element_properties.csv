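element,epsilon,r_vdw
H,2.20,1.20
C,2.55,1.70
N,3.04,1.55
O,3.44,1.52
F,3.98,1.47
S,2.58,1.80
Cl,3.16,1.75
Br,2.96,1.85
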