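# name=iridium density_g_cm3=22.42
element,fraction
Ir,1.0
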