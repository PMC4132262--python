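element,gb_radius,sasa_radius
C,1.7,1.7
N,1.55,1.55
O,1.5,1.52
S,1.8,1.8
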