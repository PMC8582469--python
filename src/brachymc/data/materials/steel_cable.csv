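# name=steel_cable density_g_cm3=5.6
# Woven stainless delivery cable: 316 composition at reduced effective density.
element,fraction
Fe,0.685
Cr,0.17
Ni,0.12
Mn,0.02
Si,0.005
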