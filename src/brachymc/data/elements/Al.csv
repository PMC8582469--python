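# Element photon interaction data: Al (Z=13)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel log-log interpolated in Z between anchor elements (approximate below ~25 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=13 A=26.982 k_edge_keV=1.56 k_yield=0.0 k_photo_fraction=0.0
E_keV,pe,compton,rayleigh,mu_en
1,19780,0.192268,2.18173,19780
1.1053,14916.3,0.19219,2.12924,14916.3
1.22168,11248.6,0.192103,2.07144,11248.6
1.35031,8482.7,0.192007,2.00857,8482.7
1.4925,6396.91,0.191901,1.941,6396.91
1.64965,4803.91,0.191784,1.86925,4803.91
1.82335,3606.81,0.191655,1.79389,3606.81
2.01534,2707.29,0.191513,1.71555,2707.29
2.22754,2025.5,0.191356,1.63482,2025.5
2.46209,1515.41,0.191183,1.55225,1515.41
2.72134,1133.78,0.190992,1.46835,1133.78
3.00788,848.185,0.190782,1.38354,848.186
3.3246,632.547,0.19055,1.29823,632.548
3.67466,471.731,0.190295,1.21279,471.732
4.06159,351.691,0.190014,1.12763,351.693
4.48925,261.747,0.189704,1.04321,261.748
4.96195,194.805,0.189364,0.960033,194.807
5.48442,144.789,0.188989,0.878695,144.791
6.0619,107.586,0.188578,0.799812,107.588
6.70019,79.8312,0.188125,0.724008,79.8336
7.40568,59.2367,0.187629,0.651863,59.2394
8.18547,43.9391,0.187084,0.583869,43.942
9.04736,32.5519,0.186486,0.5204,32.5551
10,24.1158,0.185831,0.461693,24.1193
11.053,17.8332,0.185115,0.407848,17.837
12.2168,13.1873,0.184331,0.358841,13.1915
13.5031,9.75172,0.183475,0.31454,9.7563
14.925,7.2112,0.182541,0.274737,7.21621
16.4965,5.3205,0.181524,0.239166,5.32597
18.2335,3.92505,0.180416,0.20753,3.93102
20.1534,2.89366,0.179213,0.179513,2.90017
22.2754,2.11616,0.177907,0.1548,2.12324
24.6209,1.54756,0.176493,0.133084,1.55525
27.2134,1.13174,0.174965,0.11407,1.14009
30.0788,0.827543,0.173317,0.0974828,0.836583
33.246,0.602141,0.171543,0.0830653,0.611914
36.7466,0.438132,0.169639,0.0705802,0.448679
40.6159,0.318635,0.1676,0.0598092,0.329992
44.8925,0.231081,0.165422,0.0505519,0.243284
49.6195,0.167585,0.163103,0.0426254,0.180666
54.8442,0.121261,0.160642,0.035863,0.135249
60.619,0.0876986,0.158037,0.0301141,0.102618
67.0019,0.0632523,0.155291,0.0252433,0.0791215
74.0568,0.0456205,0.152406,0.0211298,0.0624529
81.8547,0.0328842,0.149387,0.0176665,0.050686
90.4736,0.0236563,0.146239,0.0147593,0.0424267
100,0.0170179,0.14297,0.0123258,0.0367483
110.53,0.012165,0.13959,0.0102944,0.0328388
122.168,0.0086959,0.136109,0.00860303,0.030289
135.031,0.00621611,0.13254,0.00719858,0.0286962
149.25,0.00444347,0.128896,0.0060354,0.0277711
164.965,0.00312582,0.12519,0.00507464,0.0272545
182.335,0.00219703,0.121436,0.00428329,0.0270741
201.534,0.00153441,0.11765,0.00363346,0.0271015
222.754,0.000992056,0.113846,0.00310158,0.0271863
246.209,0.000641402,0.110037,0.00266783,0.0273961
272.134,0.000414691,0.106236,0.00231553,0.02766
300.788,0.000270378,0.102454,0.00203062,0.0279343
332.46,0.000240953,0.0987032,0.00180128,0.0282498
367.466,0.000214731,0.0949919,0.00161756,0.028494
406.159,0.000185361,0.0913283,0.00147107,0.0286601
448.925,0.000134065,0.0877189,0.00135482,0.0287291
496.195,9.69645e-05,0.0841694,0.00126294,0.0287376
548.442,7.01311e-05,0.0806842,0.00119062,0.0286823
606.19,5.07233e-05,0.0772667,0.00113389,0.0285613
670.019,3.66864e-05,0.07392,0.00108953,0.0283739
740.568,2.6534e-05,0.0706463,0.00105493,0.0281204
818.547,1.91911e-05,0.0674476,0.00102803,0.0278017
904.736,1.38803e-05,0.0643255,0.00100716,0.0274196
1000,1.00391e-05,0.0612816,0.000991038,0.0269766
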