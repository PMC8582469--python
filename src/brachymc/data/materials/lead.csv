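# name=lead density_g_cm3=11.35
element,fraction
Pb,1.0
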