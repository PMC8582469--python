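# name=cortical_bone density_g_cm3=1.92
# Cortical bone, standard tissue composition report.
element,fraction
H,0.034
C,0.155
N,0.042
O,0.435
Na,0.001
Mg,0.002
P,0.103
S,0.003
Ca,0.225
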