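n_treatments,a,b
4,0.93,1.07
5,0.82,0.98
6,0.81,0.99
7,0.71,0.89
8,0.71,0.89
9,0.62,0.78
10,0.62,0.78
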