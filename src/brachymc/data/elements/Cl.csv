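# Element photon interaction data: Cl (Z=17)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel log-log interpolated in Z between anchor elements (approximate below ~25 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=17 A=35.45 k_edge_keV=2.822 k_yield=0.0 k_photo_fraction=0.0
E_keV,pe,compton,rayleigh,mu_en
1,45118.9,0.191369,2.89477,45118.9
1.1053,33761.6,0.191291,2.83272,33761.6
1.22168,25263.2,0.191204,2.76366,25263.2
1.35031,18904,0.191109,2.6877,18904
1.4925,14145.5,0.191003,2.60519,14145.5
1.64965,10577.1,0.190887,2.51663,10577.1
1.82335,7908.56,0.190759,2.4227,7908.56
2.01534,5912.99,0.190617,2.32417,5912.99
2.22754,4418.44,0.190461,2.22183,4418.44
2.46209,3301.64,0.190289,2.11646,3301.64
2.72134,2467.13,0.190099,2.00878,2467.13
3.00788,1843.51,0.189889,1.89942,1843.52
3.3246,1376.77,0.189659,1.78895,1376.78
3.67466,1028.2,0.189405,1.67787,1028.21
4.06159,767.842,0.189125,1.56668,767.843
4.48925,573.236,0.188817,1.45591,573.237
4.96195,427.951,0.188478,1.34616,427.953
5.48442,319.413,0.188105,1.23812,319.415
6.0619,238.392,0.187695,1.13256,238.394
6.70019,177.879,0.187245,1.03027,177.881
7.40568,132.726,0.186751,0.932083,132.729
8.18547,99.0288,0.186208,0.838729,99.0317
9.04736,73.8708,0.185614,0.750839,73.8739
10,55.1041,0.184962,0.668879,55.1075
11.053,41.0917,0.184249,0.593141,41.0955
12.2168,30.6426,0.183469,0.523735,30.6467
13.5031,22.8505,0.182617,0.460612,22.8551
14.925,17.0399,0.181687,0.403592,17.0449
16.4965,12.6936,0.180674,0.352391,12.699
18.2335,9.45532,0.179572,0.306658,9.46126
20.1534,7.037,0.178374,0.266004,7.04348
22.2754,5.18188,0.177075,0.230016,5.18893
24.6209,3.81581,0.175668,0.198286,3.82347
27.2134,2.80987,0.174147,0.170415,2.81818
30.0788,2.06879,0.172506,0.146021,2.07779
33.246,1.51411,0.170741,0.124748,1.52384
36.7466,1.10815,0.168845,0.106266,1.11865
40.6159,0.810515,0.166816,0.0902666,0.821819
44.8925,0.590705,0.164648,0.0764698,0.602851
49.6195,0.430507,0.16234,0.0646167,0.443527
54.8442,0.31277,0.15989,0.0544715,0.326692
60.619,0.227071,0.157298,0.0458196,0.24192
67.0019,0.16421,0.154565,0.0384671,0.180005
74.0568,0.118751,0.151693,0.0322398,0.135504
81.8547,0.0857704,0.148688,0.0269825,0.103489
90.4736,0.0616931,0.145555,0.0225577,0.0803757
100,0.0443747,0.142301,0.0188445,0.0640128
110.53,0.0316254,0.138937,0.0157372,0.0522026
122.168,0.0225391,0.135473,0.013144,0.0440312
135.031,0.0160634,0.13192,0.0109856,0.0384384
149.25,0.0114482,0.128293,0.00919379,0.0346668
164.965,0.00795847,0.124604,0.00771024,0.0319743
182.335,0.00552523,0.120868,0.0064852,0.0302859
201.534,0.00379815,0.1171,0.0054765,0.0292457
222.754,0.00231615,0.113313,0.00464845,0.0283879
246.209,0.00141242,0.109522,0.00397097,0.0280419
272.134,0.000861307,0.105739,0.0034187,0.0279792
300.788,0.000532138,0.101975,0.00297034,0.0280666
332.46,0.000534063,0.0982415,0.00260792,0.0284119
367.466,0.000535994,0.0945475,0.00231634,0.028683
406.159,0.000511971,0.090901,0.00208287,0.0288535
448.925,0.000371582,0.0873086,0.00189682,0.0288328
496.195,0.000269689,0.0837756,0.00174923,0.0287763
548.442,0.000195737,0.0803067,0.00163265,0.028674
606.19,0.000142063,0.0769053,0.00154091,0.0285192
670.019,0.000103108,0.0735742,0.00146897,0.0283078
740.568,7.48341e-05,0.0703158,0.00141274,0.0280373
818.547,5.43136e-05,0.0671321,0.0013689,0.0277069
904.736,3.94201e-05,0.0640246,0.00133481,0.027317
1000,2.86106e-05,0.0609949,0.00130839,0.026869
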