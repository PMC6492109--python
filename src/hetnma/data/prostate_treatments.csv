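treatment,class
A,control
B,nonpharmacological
C,nonpharmacological
D,nonpharmacological
E,nonpharmacological
F,nonpharmacological
G,nonpharmacological
H,nonpharmacological
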