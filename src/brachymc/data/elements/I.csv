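# Element photon interaction data: I (Z=53)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel scaled from the lead anchor (Z-power law, own K edge; approximate).
# Regenerate with tools/make_physics_tables.py.
# Z=53 A=126.904 k_edge_keV=33.169 k_yield=0.884 k_photo_fraction=0.83
# k_lines_keV=28.317,28.612,32.295 k_line_weights=0.28,0.523,0.197
E_keV,pe,compton,rayleigh,mu_en
1,8606.32,0.166663,8.33408,8606.32
1.1053,6836.25,0.166595,8.23216,6836.25
1.22168,5430.22,0.166519,8.11421,5430.22
1.35031,4313.38,0.166436,7.97892,4313.38
1.4925,3426.24,0.166345,7.82529,3426.24
1.64965,2721.56,0.166243,7.65275,2721.56
1.82335,2161.81,0.166131,7.46118,2161.81
2.01534,1717.19,0.166008,7.25105,1717.19
2.22754,1364.01,0.165872,7.02336,1364.01
2.46209,1083.47,0.165722,6.77964,1083.47
2.72134,860.632,0.165557,6.52175,860.633
3.00788,683.625,0.165375,6.25182,683.626
3.3246,543.022,0.165174,5.97201,543.023
3.67466,431.338,0.164952,5.68442,431.339
4.06159,342.624,0.164709,5.39094,342.625
4.48925,272.156,0.16444,5.09325,272.157
4.96195,216.181,0.164145,4.79283,216.183
5.48442,171.719,0.163821,4.49105,171.72
6.0619,136.401,0.163464,4.18926,136.403
6.70019,108.347,0.163072,3.88896,108.349
7.40568,86.0632,0.162641,3.5918,86.0655
8.18547,68.3625,0.162169,3.29972,68.365
9.04736,54.3022,0.161651,3.01481,54.305
10,43.1338,0.161083,2.7393,43.1368
11.053,41.5736,0.160462,2.47534,41.5769
12.2168,40.0699,0.159783,2.22492,40.0735
13.5031,38.6206,0.159041,1.98964,38.6245
14.925,37.2236,0.158231,1.77067,37.228
16.4965,34.1575,0.157349,1.5687,34.1622
18.2335,31.2628,0.156389,1.38392,31.268
20.1534,28.234,0.155346,1.21613,28.2396
22.2754,21.6942,0.154214,1.06477,21.7003
24.6209,16.6692,0.152989,0.92901,16.6759
27.2134,12.8082,0.151664,0.807882,12.8154
30.0788,9.84028,0.150236,0.700304,9.84811
33.1673,7.57493,0.148736,0.607275,7.58339
33.1707,36.0615,0.148734,0.607186,12.7343
33.246,35.8432,0.148698,0.60516,12.7099
36.7466,27.4173,0.147047,0.521339,11.4111
40.6159,20.9615,0.14528,0.447768,9.89345
44.8925,15.9803,0.143392,0.383428,8.35005
49.6195,12.1829,0.141382,0.327364,6.924
54.8442,9.27043,0.139248,0.278692,5.65429
60.619,7.05208,0.136991,0.236594,4.5679
67.0019,5.3574,0.13461,0.200319,3.65484
74.0568,4.06997,0.132109,0.169181,2.90491
81.8547,3.09174,0.129492,0.142549,2.29642
90.4736,2.3354,0.126763,0.119856,1.7976
100,1.7966,0.12393,0.100584,1.42806
110.53,1.38278,0.121,0.0842734,1.13217
122.168,1.06428,0.117983,0.0705126,0.896006
135.031,0.819146,0.114889,0.0589381,0.708418
149.25,0.63047,0.11173,0.0492309,0.560018
164.965,0.4835,0.108517,0.0411126,0.441503
182.335,0.37072,0.105264,0.0343413,0.348642
201.534,0.284306,0.101982,0.0287086,0.276187
222.754,0.218589,0.0986846,0.0240351,0.220232
246.209,0.168063,0.0953827,0.0201679,0.176603
272.134,0.129216,0.0920877,0.0169764,0.142641
300.788,0.0993669,0.0888099,0.0143502,0.116256
332.46,0.0769578,0.0855584,0.0121958,0.0962679
367.466,0.0596023,0.0823414,0.0104344,0.080634
406.159,0.0462075,0.0791656,0.00899986,0.0684481
448.925,0.0360241,0.0760369,0.00783623,0.0590886
496.195,0.028085,0.0729601,0.00689659,0.0516965
548.442,0.021976,0.069939,0.00614137,0.0459176
606.19,0.0172018,0.0669767,0.00553729,0.0413063
670.019,0.0134695,0.0640757,0.00505637,0.0376014
740.568,0.010547,0.061238,0.00467524,0.0345938
818.547,0.00824106,0.0584653,0.00437443,0.0321075
904.736,0.0063933,0.055759,0.00413791,0.0299976
1000,0.00495983,0.0531204,0.00395257,0.0282286
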