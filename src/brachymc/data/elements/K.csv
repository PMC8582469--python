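# Element photon interaction data: K (Z=19)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel log-log interpolated in Z between anchor elements (approximate below ~25 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=19 A=39.098 k_edge_keV=3.608 k_yield=0.0 k_photo_fraction=0.0
E_keV,pe,compton,rayleigh,mu_en
1,21691.4,0.193927,3.30259,21691.4
1.1053,16195.9,0.193847,3.23525,16195.9
1.22168,12092.8,0.19376,3.15997,12092.8
1.35031,9029.1,0.193663,3.0768,9029.1
1.4925,6741.61,0.193556,2.98604,6741.61
1.64965,5033.65,0.193438,2.8882,5033.65
1.82335,3758.39,0.193308,2.78397,3758.39
2.01534,2806.21,0.193165,2.6742,2806.22
2.22754,2095.27,0.193007,2.55978,2095.27
2.46209,1564.44,0.192832,2.44161,1564.44
2.72134,1168.1,0.19264,2.32054,1168.1
3.00788,872.162,0.192427,2.19731,872.163
3.3246,651.203,0.192194,2.07259,651.204
3.67466,486.223,0.191936,1.94697,486.224
4.06159,1077.67,0.191653,1.82101,1077.67
4.48925,804.646,0.191341,1.6953,804.648
4.96195,600.792,0.190997,1.57049,600.794
5.48442,448.583,0.190619,1.44732,448.585
6.0619,334.936,0.190204,1.32661,334.938
6.70019,250.081,0.189748,1.20928,250.084
7.40568,186.724,0.189247,1.09625,186.727
8.18547,139.418,0.188697,0.988402,139.421
9.04736,104.097,0.188095,0.886495,104.1
10,77.7245,0.187434,0.791131,77.728
11.053,58.0332,0.186712,0.702717,58.0371
12.2168,43.3307,0.185921,0.62145,43.3349
13.5031,32.353,0.185058,0.547339,32.3577
14.925,24.1565,0.184116,0.480231,24.1616
16.4965,18.0934,0.183089,0.419843,18.0989
18.2335,13.5543,0.181972,0.365804,13.5603
20.1534,10.144,0.180758,0.317683,10.1505
22.2754,7.50175,0.179442,0.275021,7.50889
24.6209,5.54775,0.178016,0.237352,5.55551
27.2134,4.10271,0.176474,0.204218,4.11113
30.0788,3.0335,0.174812,0.17518,3.04262
33.246,2.22749,0.173023,0.149823,2.23735
36.7466,1.63564,0.171102,0.127761,1.64627
40.6159,1.20018,0.169045,0.108638,1.21164
44.8925,0.877175,0.166849,0.0921238,0.889483
49.6195,0.641098,0.16451,0.0779164,0.654292
54.8442,0.467168,0.162027,0.0657393,0.481276
60.619,0.340181,0.1594,0.0553408,0.355229
67.0019,0.24669,0.156631,0.0464926,0.262696
74.0568,0.178892,0.153721,0.0389893,0.19587
81.8547,0.129314,0.150675,0.0326473,0.147269
90.4736,0.0924739,0.1475,0.0273036,0.111406
100,0.0661294,0.144203,0.0228144,0.0860299
110.53,0.0433045,0.140794,0.0190539,0.0641567
122.168,0.0283578,0.137283,0.0159124,0.0501371
135.031,0.01857,0.133683,0.0132952,0.041244
149.25,0.0121605,0.130007,0.0111203,0.0356893
164.965,0.00989541,0.126269,0.00931782,0.0342322
182.335,0.00814504,0.122484,0.00782793,0.0332366
201.534,0.00659558,0.118665,0.00659983,0.0323832
222.754,0.00438209,0.114828,0.00559051,0.0308023
246.209,0.00291146,0.110986,0.00476367,0.0298969
272.134,0.00193437,0.107152,0.0040887,0.0294147
300.788,0.00129401,0.103338,0.00353987,0.0291965
332.46,0.00111607,0.0995546,0.0030955,0.0293665
367.466,0.000962602,0.0958113,0.00273737,0.0294858
406.159,0.000809002,0.092116,0.0024501,0.0295293
448.925,0.000588818,0.0884755,0.00222077,0.0294305
496.195,0.000428561,0.0848954,0.00203855,0.0293162
548.442,0.000311921,0.0813801,0.00189439,0.0291708
606.19,0.000227026,0.0779332,0.0017808,0.0289835
670.019,0.000165237,0.0745576,0.00169161,0.0287469
740.568,0.000120265,0.0712557,0.00162181,0.0284564
818.547,8.75327e-05,0.0680294,0.00156735,0.0281097
904.736,6.37092e-05,0.0648803,0.00152496,0.0277058
1000,4.63696e-05,0.0618102,0.00149206,0.0272455
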