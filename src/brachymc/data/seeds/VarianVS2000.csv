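# seed_id=VarianVS2000 nuclide=Ir192 active_length_mm=5.0 active_mode=volume
# Varian VariSource VS2000, Ir-192 wire source.
# Two stacked iridium cylinders modelled as one 5.0 mm x 0.34 mm dia core;
# Ni-Ti capsule OD 0.59 mm with hemispherical tip, Ni-Ti delivery wire.
# Dimensions per the published consensus descriptions.
component,kind,r_mm,half_len_mm,cz_mm,material,role
ir_core,cylinder,0.17,2.50,0.0,iridium,active
capsule,capsule,0.295,3.00,-0.40,nitinol,capsule
cable,cylinder,0.295,2.50,-6.195,nitinol,cable
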