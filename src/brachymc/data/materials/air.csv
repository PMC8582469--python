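# name=air density_g_cm3=0.0012047
# Dry air near sea level (reference compilation composition).
element,fraction
C,0.000124
N,0.755268
O,0.231781
Ar,0.012827
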