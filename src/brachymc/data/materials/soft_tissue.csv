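# name=soft_tissue density_g_cm3=1.06
# Average soft tissue, standard tissue composition report.
element,fraction
H,0.102
C,0.143
N,0.034
O,0.708
Na,0.002
P,0.003
S,0.003
Cl,0.002
K,0.003
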