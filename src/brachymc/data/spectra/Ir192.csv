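# nuclide=Ir192
# Principal gamma lines plus Pt/Os K X-rays of Ir-192 decay, photons per
# decay, from published decay data tables.  The beta continuum is omitted
# (absorbed in the source core and capsule).
energy_keV,probability
61.486,0.0120
63.000,0.0207
65.122,0.0263
66.831,0.0451
71.079,0.0024
136.343,0.00183
201.311,0.00473
205.794,0.0334
283.267,0.00266
295.957,0.2871
308.455,0.2968
316.506,0.8286
374.485,0.00727
416.469,0.00670
468.069,0.4781
484.575,0.0319
489.060,0.00438
588.581,0.0452
604.411,0.0820
612.462,0.0534
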