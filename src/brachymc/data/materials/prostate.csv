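# name=prostate density_g_cm3=1.04
# Prostate tissue, standard tissue composition report.
element,fraction
H,0.105
C,0.089
N,0.025
O,0.774
Na,0.002
P,0.001
S,0.002
K,0.002
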