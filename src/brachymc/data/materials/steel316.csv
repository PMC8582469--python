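# name=steel316 density_g_cm3=8.02
# AISI 316L stainless, simplified to the shipped element set (Mo folded into Fe).
element,fraction
Fe,0.685
Cr,0.17
Ni,0.12
Mn,0.02
Si,0.005
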