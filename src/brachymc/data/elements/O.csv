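# Element photon interaction data: O (Z=8)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Derived from the water mixture identity.
# Regenerate with tools/make_physics_tables.py.
# Z=8 A=15.999 k_edge_keV=0.533 k_yield=0.0 k_photo_fraction=0.0
E_keV,pe,compton,rayleigh,mu_en
1,4576.3,0.199543,14.3887,4576.3
1.1053,3499.86,0.199461,10.6948,3499.86
1.22168,2676.63,0.199371,7.93151,2676.63
1.35031,2047.03,0.199271,5.86551,2047.03
1.4925,1565.53,0.199161,4.32163,1565.53
1.64965,1184.9,0.19904,3.39803,1184.9
1.82335,896.325,0.198906,2.66538,896.326
2.01534,677.575,0.198759,2.10089,677.576
2.22754,508.074,0.198596,1.86337,508.075
2.46209,380.975,0.198416,1.60104,380.976
2.72134,285.671,0.198218,1.34116,285.672
3.00788,214.163,0.198,1.10283,214.164
3.3246,159.306,0.197759,0.99524,159.308
3.67466,118.501,0.197495,0.857804,118.503
4.06159,88.08,0.197203,0.726841,88.0816
4.48925,65.1882,0.196882,0.651072,65.1901
4.96195,48.2459,0.196528,0.552773,48.2478
5.48442,35.5873,0.196139,0.4916,35.5895
6.0619,26.2324,0.195712,0.421041,26.2348
6.70019,19.2703,0.195243,0.384946,19.2732
7.40568,14.1559,0.194727,0.325463,14.1589
8.18547,10.3894,0.194162,0.270832,10.3926
9.04736,7.60173,0.193542,0.242376,7.60536
10,5.56204,0.192862,0.196948,5.56566
11.053,4.05103,0.192118,0.20888,4.0564
12.2168,2.95051,0.191305,0.188337,2.95642
13.5031,2.14896,0.190417,0.151601,2.15472
14.925,1.56516,0.189448,0.108659,1.57041
16.4965,1.13489,0.188391,0.108553,1.14157
18.2335,0.822704,0.187242,0.0919117,0.829722
20.1534,0.596226,0.185993,0.0694386,0.603278
22.2754,0.430608,0.184638,0.0789361,0.440541
24.6209,0.310995,0.183171,0.071659,0.321703
27.2134,0.224608,0.181585,0.0550087,0.234922
30.0788,0.162204,0.179874,0.0345583,0.171663
33.246,0.116784,0.178034,0.0351992,0.128529
36.7466,0.0840821,0.176057,0.0290278,0.0962331
40.6159,0.0605222,0.173941,0.0206834,0.0726009
44.8925,0.0435026,0.171681,0.018829,0.0571277
49.6195,0.0312691,0.169274,0.0140857,0.0449522
54.8442,0.0224606,0.166719,0.0123394,0.0375382
60.619,0.0161315,0.164016,0.00975349,0.0317743
67.0019,0.011579,0.161166,0.00890241,0.0290057
74.0568,0.00831129,0.158172,0.00726943,0.0264784
81.8547,0.00596914,0.155039,0.00553254,0.0245623
90.4736,0.00429519,0.151772,0.00465926,0.0240502
100,0.00309067,0.148379,0.00364484,0.0235487
110.53,0.00222134,0.144871,0.00308297,0.0239128
122.168,0.00159653,0.141259,0.00253827,0.0242825
135.031,0.00114746,0.137555,0.00206198,0.0246579
149.25,0.000824709,0.133772,0.00168503,0.0250392
164.965,0.000592738,0.129926,0.0013104,0.0256176
182.335,0.000426015,0.126031,0.00105917,0.0262198
201.534,0.000306187,0.122102,0.000911505,0.0268245
222.754,0.000220064,0.118153,0.000599904,0.0273005
246.209,0.000158165,0.1142,0.000422245,0.0277849
272.134,0.000113677,0.110255,0.000366614,0.0282779
300.788,8.17024e-05,0.10633,0.000411937,0.0287734
332.46,5.87214e-05,0.102438,0.000249803,0.0290397
367.466,4.22045e-05,0.0985859,0.000195699,0.0293085
406.159,3.03334e-05,0.0947836,0.000208907,0.0295501
448.925,2.18013e-05,0.0910377,0.000157482,0.0296284
496.195,1.56691e-05,0.0873539,0.000194008,0.029707
548.442,1.12618e-05,0.0837368,0.000134132,0.0296432
606.19,8.0941e-06,0.0801901,0.000126062,0.02955
670.019,5.81742e-06,0.0767167,4.77146e-05,0.0293023
740.568,4.18112e-06,0.0733192,5.01868e-05,0.0290566
818.547,3.00507e-06,0.0699994,8.62054e-05,0.0287718
904.736,2.15981e-06,0.0667592,6.57417e-05,0.0283525
1000,1.55231e-06,0.0636002,0.000115673,0.0279394
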