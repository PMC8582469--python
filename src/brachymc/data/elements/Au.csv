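# Element photon interaction data: Au (Z=79)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel scaled from the lead anchor (Z-power law, own K edge; approximate).
# Regenerate with tools/make_physics_tables.py.
# Z=79 A=196.967 k_edge_keV=80.725 k_yield=0.964 k_photo_fraction=0.8
# k_lines_keV=66.99,68.804,77.98 k_line_weights=0.29,0.5,0.21
E_keV,pe,compton,rayleigh,mu_en
1,23320.2,0.160056,12.092,23320.2
1.1053,18523.9,0.159991,11.9734,18523.9
1.22168,14714,0.159918,11.8346,14714
1.35031,11687.8,0.159838,11.6735,11687.8
1.4925,9283.94,0.15975,11.4882,9283.94
1.64965,7374.49,0.159653,11.277,7374.49
1.82335,5857.77,0.159546,11.039,5857.77
2.01534,4652.99,0.159427,10.7737,4652.99
2.22754,3696,0.159297,10.4815,3696
2.46209,2935.84,0.159153,10.1637,2935.84
2.72134,2332.02,0.158994,9.82206,2332.02
3.00788,1852.39,0.158819,9.45925,1852.39
3.3246,1471.4,0.158626,9.07818,1471.41
3.67466,1168.78,0.158413,8.68195,1168.78
4.06159,928.394,0.158179,8.27362,928.395
4.48925,737.449,0.157922,7.856,737.451
4.96195,585.777,0.157638,7.43161,585.778
5.48442,465.299,0.157326,7.00263,465.301
6.0619,369.6,0.156984,6.57106,369.602
6.70019,293.584,0.156607,6.13884,293.586
7.40568,233.202,0.156194,5.70802,233.204
8.18547,185.239,0.15574,5.28088,185.241
9.04736,147.14,0.155243,4.86006,147.143
10,116.878,0.154698,4.44849,116.881
11.053,112.65,0.154101,4.04932,112.653
12.2168,108.576,0.153449,3.66571,108.579
13.5031,104.648,0.152736,3.30057,104.652
14.925,100.863,0.151959,2.95642,100.867
16.4965,92.5551,0.151111,2.63515,92.5596
18.2335,84.7114,0.150189,2.33796,84.7164
20.1534,76.5045,0.149188,2.06537,76.5099
22.2754,58.7839,0.148101,1.81725,58.7898
24.6209,45.1679,0.146924,1.59295,45.1743
27.2134,34.7057,0.145652,1.39141,34.7127
30.0788,26.6638,0.14428,1.2113,26.6713
33.246,20.3958,0.142803,1.05109,20.4039
36.7466,15.6012,0.141218,0.909218,15.61
40.6159,11.9277,0.13952,0.784071,11.9371
44.8925,9.09325,0.137708,0.674093,9.10341
49.6195,6.93239,0.135777,0.5778,6.94328
54.8442,5.27513,0.133728,0.493792,5.28678
60.619,4.01283,0.13156,0.420771,4.02525
67.0019,3.04851,0.129274,0.357535,3.06172
74.0568,2.31593,0.126872,0.30298,2.32994
80.721,1.82797,0.124715,0.262198,1.84268
80.729,8.70223,0.124713,0.262154,2.88067
81.8547,8.37756,0.124359,0.25609,2.85112
90.4736,6.32814,0.121738,0.215939,2.55682
100,4.86816,0.119017,0.181684,2.24886
110.53,3.74687,0.116203,0.152562,1.9287
122.168,2.88385,0.113306,0.127887,1.62376
135.031,2.2196,0.110335,0.107049,1.34835
149.25,1.70836,0.107301,0.0895039,1.10805
164.965,1.31012,0.104216,0.0747755,0.90022
182.335,1.00452,0.101091,0.0624466,0.726952
201.534,0.770372,0.0979396,0.0521544,0.584695
222.754,0.592303,0.0947725,0.0435853,0.470145
246.209,0.455394,0.0916015,0.0364695,0.377524
272.134,0.350131,0.0884371,0.030576,0.303152
300.788,0.26925,0.0852892,0.025708,0.243814
332.46,0.208529,0.0821667,0.0216983,0.197886
367.466,0.161502,0.0790772,0.0184055,0.161248
406.159,0.125206,0.0760273,0.0157103,0.13222
448.925,0.0976131,0.0730227,0.0135123,0.109645
496.195,0.0761008,0.0700678,0.011727,0.0916394
548.442,0.0595475,0.0671665,0.0102832,0.0774875
606.19,0.0466109,0.0643216,0.00912089,0.0661818
670.019,0.0364977,0.0615356,0.00818974,0.0571381
740.568,0.0285788,0.0588104,0.00744731,0.0498765
818.547,0.0223305,0.0561476,0.00685806,0.0439813
904.736,0.0173236,0.0535486,0.00639238,0.0391012
1000,0.0134394,0.0510146,0.0060258,0.0351604
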