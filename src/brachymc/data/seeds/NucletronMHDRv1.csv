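# seed_id=NucletronMHDRv1 nuclide=Ir192 active_length_mm=3.5 active_mode=volume
# Nucletron microSelectron HDR v1 (classic), Ir-192 wire source.
# Iridium core 3.5 mm x 0.6 mm dia; stainless capsule OD 1.1 mm, overall
# length 5.0 mm, distal tip 0.35 mm beyond the core; woven stainless cable
# stub on the -Z side.  Dimensions per the published consensus descriptions.
component,kind,r_mm,half_len_mm,cz_mm,material,role
ir_core,cylinder,0.30,1.75,0.0,iridium,active
capsule,capsule,0.55,1.95,-0.40,steel316,capsule
cable,cylinder,0.45,2.50,-5.40,steel_cable,cable
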