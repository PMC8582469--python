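# name=alumina density_g_cm3=3.97
# Al2O3 ceramic (seed cores).
element,fraction
Al,0.529251
O,0.470749
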