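# seed_id=BebigIsoseedI25S06 nuclide=I125 active_length_mm=3.5 active_mode=volume
# Bebig Isoseed I25.S06, LDR I-125.
# Gold X-ray marker 3.5 mm x 0.17 mm dia centred in an alumina ceramic core
# 3.5 mm x 0.6 mm dia carrying the activity in its volume; Ti capsule
# OD 0.8 mm, 0.05 mm wall, 4.5 mm overall.  Dimensions per the published
# consensus seed descriptions.
component,kind,r_mm,half_len_mm,cz_mm,material,role
gold_marker,cylinder,0.085,1.75,0.0,gold,marker
ceramic_core,cylinder,0.30,1.75,0.0,alumina,active
cavity,capsule,0.35,1.85,0.0,air,cavity
capsule,capsule,0.40,1.85,0.0,titanium,capsule
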