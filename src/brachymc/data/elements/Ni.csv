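# Element photon interaction data: Ni (Z=28)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel log-log interpolated in Z between anchor elements (approximate below ~25 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=28 A=58.693 k_edge_keV=8.333 k_yield=0.414 k_photo_fraction=0.86
# k_lines_keV=7.48 k_line_weights=1
E_keV,pe,compton,rayleigh,mu_en
1,13675,0.190375,4.88707,13675
1.1053,10414.1,0.190297,4.80408,10414.1
1.22168,7930.75,0.190211,4.70996,7930.75
1.35031,6039.59,0.190116,4.6044,6039.59
1.4925,4599.39,0.190011,4.48738,4599.4
1.64965,3502.63,0.189896,4.35921,3502.63
1.82335,2667.39,0.189768,4.22055,2667.4
2.01534,2031.33,0.189627,4.07234,2031.33
2.22754,1546.94,0.189472,3.91574,1546.94
2.46209,1178.06,0.189301,3.75203,1178.06
2.72134,897.14,0.189112,3.58252,897.141
3.00788,683.209,0.188903,3.40847,683.21
3.3246,520.292,0.188674,3.23099,520.293
3.67466,396.223,0.188421,3.05109,396.225
4.06159,301.74,0.188143,2.86965,301.742
4.48925,229.788,0.187836,2.68749,229.789
4.96195,174.993,0.187499,2.50544,174.995
5.48442,133.264,0.187128,2.32439,133.266
6.0619,101.486,0.186721,2.14539,101.488
6.70019,77.2858,0.186273,1.96959,77.2882
7.40568,350.704,0.185781,1.79829,350.707
8.18547,267.075,0.185241,1.63283,267.078
8.33258,254.439,0.18514,1.6041,254.442
8.33342,254.37,0.18514,1.60393,173.082
9.04736,203.389,0.18465,1.47449,143.523
10,154.889,0.184002,1.32446,113.643
11.053,117.954,0.183292,1.18367,89.5373
12.2168,89.827,0.182516,1.05279,70.2495
13.5031,68.407,0.181669,0.9322,54.9198
14.925,52.0947,0.180744,0.821985,42.804
16.4965,39.2778,0.179736,0.721985,32.9422
18.2335,29.5986,0.17864,0.631843,25.2814
20.1534,22.2948,0.177448,0.551052,19.3551
22.2754,16.7034,0.176155,0.479011,14.7134
24.6209,12.5143,0.174755,0.415062,11.1683
27.2134,11.8191,0.173242,0.358534,10.6707
30.0788,8.84007,0.171611,0.308756,8.06632
33.246,6.5865,0.169854,0.265085,6.06856
36.7466,4.90742,0.167969,0.22691,4.56221
40.6159,3.65357,0.16595,0.193662,3.42525
44.8925,2.70845,0.163793,0.16481,2.55985
49.6195,2.00781,0.161497,0.139867,1.913
54.8442,1.48337,0.15906,0.118384,1.42519
60.619,1.0952,0.156481,0.0999519,1.06186
67.0019,0.806023,0.153762,0.084195,0.789699
74.0568,0.5932,0.150905,0.0707735,0.588534
81.8547,0.436195,0.147916,0.059381,0.43963
90.4736,0.319818,0.144799,0.0497426,0.328989
100,0.23449,0.141562,0.0416141,0.247781
110.53,0.17038,0.138216,0.0347797,0.186745
122.168,0.123798,0.134769,0.0290499,0.14248
135.031,0.0899516,0.131235,0.0242595,0.110436
149.25,0.0653588,0.127627,0.0202653,0.0872905
164.965,0.0472278,0.123957,0.0169438,0.0703564
182.335,0.0341165,0.120241,0.0141889,0.0582503
201.534,0.0246127,0.116492,0.01191,0.0496029
222.754,0.0174759,0.112725,0.0100299,0.0432033
246.209,0.0124084,0.108953,0.00848343,0.0387655
272.134,0.0088104,0.10519,0.00721529,0.0357012
300.788,0.00624137,0.101445,0.00617899,0.0335776
332.46,0.00406076,0.0977314,0.00533535,0.0317613
367.466,0.00264201,0.0940566,0.00465143,0.0306237
406.159,0.00183451,0.090429,0.00409947,0.0300168
448.925,0.00182809,0.0868552,0.0036561,0.0301307
496.195,0.00182169,0.0833406,0.00330168,0.0301705
548.442,0.00137609,0.0798897,0.00301968,0.0296998
606.19,0.00101597,0.0765059,0.00279631,0.0292413
670.019,0.000750091,0.0731922,0.0026201,0.0288053
740.568,0.000553793,0.0699507,0.00248162,0.028369
818.547,0.000408866,0.0667835,0.00237314,0.0279165
904.736,0.000301867,0.0636921,0.00228842,0.0274369
1000,0.000222869,0.0606782,0.00222243,0.0269233
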