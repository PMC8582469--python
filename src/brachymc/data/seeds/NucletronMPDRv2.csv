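# seed_id=NucletronMPDRv2 nuclide=Ir192 active_length_mm=1.0 active_mode=volume
# Nucletron microSelectron PDR v2, Ir-192 source.
# Short iridium core 1.0 mm x 0.6 mm dia; stainless capsule OD 0.9 mm,
# overall length 2.7 mm; stainless cable stub.  Dimensions per the published
# consensus descriptions.
component,kind,r_mm,half_len_mm,cz_mm,material,role
ir_core,cylinder,0.30,0.50,0.0,iridium,active
capsule,capsule,0.45,0.90,0.0,steel316,capsule
cable,cylinder,0.45,2.50,-3.85,steel_cable,cable
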