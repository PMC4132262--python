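element,rmin_half,epsilon
C,2.0,0.1
N,1.85,0.2
O,1.7,0.12
S,2.0,0.45
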