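# name=water density_g_cm3=0.998
# Liquid water at 22 C (reference compilation composition).
element,fraction
H,0.111894
O,0.888106
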