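# seed_id=SpecM19 nuclide=Ir192 active_length_mm=3.3 active_mode=volume
# SPEC HDR M-19 industrial/HDR Ir-192 source.
# Stack of iridium discs modelled as one 3.3 mm x 2.7 mm dia core in a
# stainless capsule; approximate vendor dimensions (no consensus report).
component,kind,r_mm,half_len_mm,cz_mm,material,role
ir_core,cylinder,1.35,1.65,0.0,iridium,active
capsule,capsule,1.60,2.00,0.0,steel316,capsule
cable,cylinder,1.00,2.50,-6.10,steel_cable,cable
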