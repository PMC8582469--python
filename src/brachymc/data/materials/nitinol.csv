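# name=nitinol density_g_cm3=6.45
# Ni-Ti alloy capsule/wire material.
element,fraction
Ni,0.56
Ti,0.44
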