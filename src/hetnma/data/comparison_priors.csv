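context,comparison_type,m,s
smoking,nonpharm_vs_nonpharm,-2.26,1.45
smoking,nonpharm_vs_control,-2.92,1.71
prostate,nonpharm_vs_nonpharm,-3.50,1.26
prostate,nonpharm_vs_control,-4.17,1.55
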