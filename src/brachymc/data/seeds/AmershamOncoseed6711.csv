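# seed_id=AmershamOncoseed6711 nuclide=I125 active_length_mm=3.0 active_mode=surface
# Amersham Health OncoSeed 6711, LDR I-125.
# Silver rod 3.0 mm x 0.5 mm dia with a radioactive AgI surface layer
# (modelled as surface emission); Ti capsule OD 0.8 mm, 0.05 mm side wall,
# 4.6 mm overall length with hemispherical end welds.  Dimensions per the
# published consensus seed descriptions (AAPM TG-43U1 and refs therein).
# Components are listed innermost first; capsule kind = cylinder + hemi caps,
# half_len_mm is the half length of the cylindrical part.
component,kind,r_mm,half_len_mm,cz_mm,material,role
silver_rod,cylinder,0.25,1.50,0.0,silver,active|marker
cavity,capsule,0.35,1.55,0.0,air,cavity
capsule,capsule,0.40,1.90,0.0,titanium,capsule
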