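# nuclide=I125
# Principal photon lines of I-125 decay (Te K X-rays + 35.5 keV gamma),
# photons per decay, from published decay data tables.
energy_keV,probability
27.202,0.406
27.472,0.757
30.980,0.202
31.710,0.0439
35.492,0.0668
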