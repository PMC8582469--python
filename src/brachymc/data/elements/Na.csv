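# Element photon interaction data: Na (Z=11)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel log-log interpolated in Z between anchor elements (approximate below ~25 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=11 A=22.99 k_edge_keV=1.072 k_yield=0.0 k_photo_fraction=0.0
E_keV,pe,compton,rayleigh,mu_en
1,11719.9,0.190938,1.80933,11719.9
1.1053,8880.96,0.19086,1.76272,8880.96
1.22168,6729.69,0.190774,1.71175,6729.69
1.35031,5099.53,0.190678,1.65668,5099.53
1.4925,3864.26,0.190573,1.59789,3864.26
1.64965,2909.77,0.190457,1.53585,2909.77
1.82335,2190.32,0.190329,1.47107,2190.32
2.01534,1648.08,0.190188,1.40406,1648.08
2.22754,1233.99,0.190032,1.33531,1233.99
2.46209,923.939,0.18986,1.26525,923.94
2.72134,691.792,0.189671,1.19429,691.793
3.00788,517.908,0.189462,1.12275,517.909
3.3246,385.897,0.189232,1.05096,385.898
3.67466,287.535,0.188978,0.979253,287.536
4.06159,214.144,0.188699,0.907986,214.146
4.48925,159.071,0.188392,0.837571,159.072
4.96195,118.161,0.188053,0.768475,118.163
5.48442,87.594,0.187682,0.701208,87.5959
6.0619,64.9078,0.187273,0.636299,64.9099
6.70019,47.9967,0.186824,0.574255,47.9991
7.40568,35.4917,0.18633,0.515526,35.4943
8.18547,26.2302,0.185789,0.460474,26.2331
9.04736,19.3494,0.185196,0.40935,19.3526
10,14.2736,0.184546,0.362288,14.2771
11.053,10.5,0.183834,0.319312,10.5038
12.2168,7.72411,0.183056,0.28035,7.72827
13.5031,5.68206,0.182206,0.245251,5.68661
14.925,4.17987,0.181278,0.213812,4.18485
16.4965,3.06555,0.180268,0.185793,3.07099
18.2335,2.24795,0.179168,0.160934,2.25388
20.1534,1.64752,0.177973,0.138968,1.65398
22.2754,1.19967,0.176676,0.119634,1.2067
24.6209,0.873565,0.175272,0.102678,0.881205
27.2134,0.636103,0.173755,0.0878628,0.644392
30.0788,0.463137,0.172118,0.0749642,0.472115
33.246,0.335768,0.170356,0.0637759,0.345474
36.7466,0.243427,0.168465,0.0541075,0.2539
40.6159,0.176407,0.16644,0.045784,0.187685
44.8925,0.127543,0.164277,0.0386452,0.139661
49.6195,0.0922135,0.161975,0.032545,0.105204
54.8442,0.0665559,0.15953,0.0273511,0.0804468
60.619,0.0480196,0.156944,0.0229439,0.0628353
67.0019,0.0345768,0.154217,0.0192167,0.0503362
74.0568,0.0248972,0.151352,0.0160745,0.0416131
81.8547,0.0179239,0.148353,0.0134334,0.0356026
90.4736,0.0128953,0.145227,0.0112198,0.0315358
100,0.00927744,0.141981,0.00936969,0.0288713
110.53,0.00664421,0.138624,0.00782757,0.027175
122.168,0.00475838,0.135168,0.00654553,0.026202
135.031,0.0034078,0.131623,0.00548249,0.0257324
149.25,0.00244056,0.128004,0.00460338,0.0256068
164.965,0.00172957,0.124323,0.00387837,0.0256913
182.335,0.00122502,0.120596,0.00328219,0.0259299
201.534,0.000864044,0.116836,0.00279349,0.0262543
222.754,0.000579358,0.113058,0.0023943,0.0265924
246.209,0.00038847,0.109275,0.00206947,0.026958
272.134,0.000260476,0.105501,0.00180626,0.0273173
300.788,0.000175621,0.101745,0.00159394,0.0276481
332.46,0.000145345,0.0980203,0.00142349,0.0279604
367.466,0.000120288,0.0943346,0.0012873,0.0282039
406.159,9.74926e-05,0.0906963,0.001179,0.0283752
448.925,7.03604e-05,0.087112,0.00109326,0.0284675
496.195,5.0779e-05,0.083587,0.00102565,0.0284932
548.442,3.66472e-05,0.0801259,0.000972533,0.0284508
606.19,2.64482e-05,0.0767321,0.000930939,0.0283397
670.019,1.90877e-05,0.0734085,0.000898465,0.0281602
740.568,1.37756e-05,0.0701575,0.000873181,0.0279132
818.547,9.94181e-06,0.0669809,0.000853549,0.0276002
904.736,7.175e-06,0.0638804,0.000838351,0.0272233
1000,5.17819e-06,0.0608576,0.000826625,0.0267851
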