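# name=lung density_g_cm3=0.26
# Inflated lung, standard tissue composition report.
element,fraction
H,0.103
C,0.105
N,0.031
O,0.749
Na,0.002
P,0.002
S,0.003
Cl,0.003
K,0.002
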