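# Element photon interaction data: Cu (Z=29)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel log-log interpolated in Z between anchor elements (approximate below ~25 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=29 A=63.546 k_edge_keV=8.979 k_yield=0.445 k_photo_fraction=0.86
# k_lines_keV=8.05 k_line_weights=1
E_keV,pe,compton,rayleigh,mu_en
1,14015.6,0.182116,4.85093,14015.6
1.1053,10672.7,0.182042,4.76996,10672.7
1.22168,8127.17,0.181959,4.67802,8127.17
1.35031,6188.75,0.181868,4.57477,6188.75
1.4925,4712.67,0.181768,4.46014,4712.67
1.64965,3588.65,0.181657,4.33442,3588.65
1.82335,2732.72,0.181535,4.19821,2732.72
2.01534,2080.93,0.181401,4.05241,2080.94
2.22754,1584.61,0.181252,3.89816,1584.61
2.46209,1206.66,0.181088,3.73671,1206.66
2.72134,918.861,0.180907,3.56938,918.862
3.00788,699.703,0.180708,3.39739,699.704
3.3246,532.817,0.180489,3.22189,532.818
3.67466,405.734,0.180247,3.04389,405.735
4.06159,308.962,0.179981,2.86426,308.964
4.48925,235.271,0.179687,2.68382,235.273
4.96195,179.157,0.179365,2.50338,179.158
5.48442,136.426,0.17901,2.32384,136.428
6.0619,103.887,0.17862,2.14619,103.889
6.70019,79.1088,0.178192,1.97158,79.111
7.40568,318.067,0.177721,1.80127,318.07
8.18547,242.205,0.177205,1.63659,242.207
8.97855,188.309,0.176684,1.49059,188.312
8.97945,188.257,0.176684,1.49043,123.672
9.04736,184.436,0.176639,1.47883,121.637
10,140.446,0.176019,1.32916,97.1818
11.053,106.948,0.17534,1.18856,77.1428
12.2168,81.44,0.174598,1.05772,60.9071
13.5031,62.0157,0.173787,0.937036,47.8712
14.925,47.2243,0.172903,0.826639,37.4813
16.4965,35.5833,0.171939,0.726394,28.9433
18.2335,26.797,0.17089,0.635965,22.275
20.1534,20.173,0.16975,0.554866,17.0954
22.2754,15.121,0.168513,0.482508,13.0364
24.6209,11.3342,0.167174,0.418247,9.92325
27.2134,11.9507,0.165727,0.361415,10.6057
30.0788,8.93656,0.164166,0.311348,8.02982
33.246,6.66767,0.162485,0.267405,6.05906
36.7466,4.97482,0.160682,0.228976,4.56773
40.6159,3.70881,0.15875,0.195491,3.43826
44.8925,2.7528,0.156687,0.166422,2.57545
49.6195,2.04322,0.154491,0.14128,1.92875
54.8442,1.51121,0.152159,0.119617,1.43957
60.619,1.117,0.149692,0.101021,1.07436
67.0019,0.823014,0.147091,0.0851174,0.800203
74.0568,0.606403,0.144359,0.0715656,0.597121
81.8547,0.446419,0.141499,0.0600578,0.44648
90.4736,0.327694,0.138517,0.0503183,0.334315
100,0.240543,0.135421,0.0421015,0.251821
110.53,0.174611,0.132219,0.0351904,0.189326
122.168,0.12675,0.128923,0.0293944,0.144007
135.031,0.0920082,0.125542,0.0245472,0.111202
149.25,0.0667889,0.12209,0.0205043,0.0875062
164.965,0.0482227,0.118579,0.0171413,0.0701768
182.335,0.0348078,0.115024,0.0143511,0.0577831
201.534,0.0250932,0.111438,0.0120422,0.0489267
222.754,0.0178173,0.107835,0.0101369,0.042382
246.209,0.0126511,0.104227,0.00856906,0.0378347
272.134,0.00898281,0.100626,0.00728292,0.0346878
300.788,0.0063641,0.0970444,0.00623146,0.0325021
332.46,0.00415301,0.0934915,0.00537509,0.0306445
367.466,0.00271012,0.0899761,0.00468049,0.0294735
406.159,0.00188867,0.0865059,0.00411961,0.0288455
448.925,0.00189581,0.0830872,0.00366884,0.0289679
496.195,0.00190298,0.0797251,0.00330828,0.0290195
548.442,0.00143984,0.0764238,0.00302125,0.0285331
606.19,0.00106427,0.0731869,0.00279378,0.028064
670.019,0.000786667,0.0700169,0.00261426,0.027624
740.568,0.000581473,0.066916,0.00247311,0.0271895
818.547,0.000429802,0.0638862,0.0023625,0.0267437
904.736,0.000317692,0.060929,0.00227609,0.0262753
1000,0.000234826,0.0580458,0.00220877,0.0257767
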