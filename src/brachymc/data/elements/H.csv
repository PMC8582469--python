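# Element photon interaction data: H (Z=1)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Anchored element (totals and mu_en transcribed).
# Regenerate with tools/make_physics_tables.py.
# Z=1 A=1.008 k_edge_keV=0.0136 k_yield=0.0 k_photo_fraction=0.0
E_keV,pe,compton,rayleigh,mu_en
1,6.81923,0.395893,0.00187819,6.82
1.1053,4.87461,0.395731,0.0802775,4.87581
1.22168,3.48453,0.395552,0.0868156,3.48586
1.35031,2.49085,0.395355,0.0548101,2.49214
1.4925,1.78054,0.395137,0.00476313,1.7817
1.64965,1.26996,0.394896,0.0353705,1.27148
1.82335,0.905678,0.394631,0.0289903,0.907289
2.01534,0.64578,0.394338,0.00628774,0.647408
2.22754,0.459504,0.394015,0.041039,0.461942
2.46209,0.326959,0.393658,0.044127,0.329607
2.72134,0.232647,0.393266,0.0278566,0.235183
3.00788,0.165532,0.392833,0.00175844,0.16784
3.3246,0.117563,0.392355,0.0106114,0.120601
3.67466,0.0834949,0.39183,0.00841087,0.0866582
4.06159,0.0592861,0.391251,0.00155387,0.0624589
4.48925,0.0420447,0.390614,0.00333132,0.0457875
4.96195,0.0298174,0.389913,0.000732056,0.033566
5.48442,0.0219728,0.389141,0.000458001,0.0262791
6.0619,0.0162236,0.387513,1e-08,0.0208119
6.70019,0.0118513,0.387362,2.6685e-05,0.0173794
7.40568,0.00865737,0.386137,1e-08,0.0145131
8.18547,0.0061763,0.384603,1e-08,0.0123129
9.04736,0.0040687,0.383987,2.46342e-05,0.0110184
10,0.0026803,0.382639,8.05671e-05,0.00986
11.053,0.00189383,0.381164,0.000100513,0.0101345
12.2168,0.00133813,0.37955,4.07362e-05,0.0104167
13.5031,0.000945491,0.377768,1e-08,0.0107067
14.925,0.00066806,0.375842,1e-08,0.0110048
16.4965,0.000470727,0.373634,1e-08,0.0117992
18.2335,0.000331634,0.371372,1e-08,0.0126791
20.1534,0.00023332,0.369011,1.66503e-05,0.0136315
22.2754,0.000161434,0.365975,1e-08,0.0147464
24.6209,0.000111696,0.362926,1e-08,0.0159524
27.2134,7.72825e-05,0.359889,1e-08,0.0172571
30.0788,5.3616e-05,0.356843,1e-08,0.0186669
33.246,4.11116e-05,0.352918,1e-08,0.0201327
36.7466,3.15235e-05,0.349034,1e-08,0.0217136
40.6159,2.43454e-05,0.34506,1e-08,0.0234005
44.8925,1.95653e-05,0.340415,1e-08,0.0251101
49.6195,1.57237e-05,0.335832,1e-08,0.0269446
54.8442,1.20609e-05,0.330635,1e-08,0.0287834
60.619,8.98301e-06,0.325372,1e-08,0.0307161
67.0019,5.34841e-06,0.319404,1e-08,0.032592
74.0568,3.1844e-06,0.313544,1e-08,0.0345826
81.8547,2.04763e-06,0.307555,1e-08,0.0366318
90.4736,1.70623e-06,0.300905,1e-08,0.0385791
100,1.42175e-06,0.294385,1.35819e-05,0.04063
110.53,1.03644e-06,0.286877,1e-08,0.0423654
122.168,7.55558e-07,0.279547,1e-08,0.044175
135.031,5.50795e-07,0.272404,1e-08,0.0460618
149.25,4.01524e-07,0.265405,3.88036e-05,0.0480293
164.965,2.92707e-07,0.257545,1e-08,0.0495452
182.335,2.13381e-07,0.249825,1e-08,0.0510801
201.534,1.55553e-07,0.24225,1.05627e-05,0.0526198
222.754,1.13396e-07,0.234039,1e-08,0.0536775
246.209,8.26648e-08,0.226095,1e-08,0.0547564
272.134,6.02619e-08,0.218422,1e-08,0.055857
300.788,4.39303e-08,0.21096,2.9163e-05,0.0569648
332.46,3.20248e-08,0.203102,1e-08,0.0575338
367.466,2.33458e-08,0.195511,1e-08,0.0581085
406.159,1.70188e-08,0.188051,7.80929e-05,0.0586273
448.925,1.24066e-08,0.180619,1.47654e-05,0.0588065
496.195,9.04428e-09,0.17331,0.000126882,0.0589863
548.442,6.59319e-09,0.166134,4.54967e-05,0.0588731
606.19,4.80637e-09,0.159097,6.6521e-05,0.0587009
670.019,3.5038e-09,0.152159,1e-08,0.0582244
740.568,2.55424e-09,0.145462,1e-08,0.0577518
818.547,1.86202e-09,0.138879,9.1772e-05,0.0571993
904.736,1.35739e-09,0.13245,3.35328e-05,0.0563737
1000,9.89525e-10,0.126183,0.000117102,0.05556
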