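# Element photon interaction data: C (Z=6)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Anchored element (totals transcribed, E>=10 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=6 A=12.011 k_edge_keV=0.284 k_yield=0.0 k_photo_fraction=0.0
E_keV,pe,compton,rayleigh,mu_en
1,4032.54,0.199347,0.974254,4032.54
1.1053,2898.01,0.199266,0.942851,2898.01
1.22168,2082.68,0.199176,0.909336,2082.68
1.35031,1496.73,0.199076,0.873975,1496.73
1.4925,1075.64,0.198967,0.837057,1075.64
1.64965,773.014,0.198845,0.798875,773.014
1.82335,555.532,0.198712,0.759707,555.532
2.01534,399.237,0.198564,0.719803,399.238
2.22754,286.914,0.198402,0.679381,286.915
2.46209,206.193,0.198222,0.638637,206.194
2.72134,148.182,0.198024,0.597756,148.183
3.00788,106.492,0.197806,0.556922,106.493
3.3246,76.5313,0.197566,0.516344,76.5326
3.67466,54.9998,0.197301,0.476255,55.0012
4.06159,39.526,0.19701,0.436923,39.5275
4.48925,28.4056,0.196689,0.398638,28.4073
4.96195,20.4139,0.196336,0.361701,20.4158
5.48442,14.6706,0.195948,0.3264,14.6727
6.0619,10.5431,0.195521,0.292992,10.5454
6.70019,7.5769,0.195052,0.26168,7.57938
7.40568,5.44519,0.194537,0.232608,5.44792
8.18547,3.91323,0.193972,0.205849,3.91623
9.04736,2.81227,0.193352,0.181418,2.81556
10,2.02106,0.192674,0.15927,2.02467
11.053,1.45034,0.191931,0.175974,1.45431
12.2168,1.04079,0.191118,0.161276,1.04513
13.5031,0.746891,0.190231,0.130372,0.751642
14.925,0.535982,0.189262,0.0926953,0.541177
16.4965,0.380796,0.188207,0.0924263,0.386471
18.2335,0.2704,0.187059,0.0789317,0.27659
20.1534,0.191729,0.185811,0.0599414,0.198475
22.2754,0.133577,0.184457,0.0643336,0.140918
24.6209,0.0930625,0.182992,0.0581434,0.101039
27.2134,0.0648362,0.181407,0.0458519,0.0734902
30.0788,0.0451278,0.179698,0.0308827,0.0545009
33.246,0.0303091,0.177859,0.0294913,0.0404428
36.7466,0.0203565,0.175885,0.0246432,0.0312913
40.6159,0.0135645,0.173771,0.0187921,0.0253394
44.8925,0.00865113,0.171513,0.0165694,0.0213029
49.6195,0.00551748,0.169108,0.0131413,0.0190798
54.8442,0.00313132,0.166556,0.0113315,0.017634
60.619,0.00177596,0.163856,0.00913677,0.0172442
67.0019,0.00108977,0.161009,0.00757065,0.0175433
74.0568,0.000668709,0.158018,0.0060322,0.0181209
81.8547,0.000408824,0.154887,0.00469083,0.0188661
90.4736,0.000246854,0.151623,0.0037641,0.0197084
100,0.000149055,0.148234,0.00301679,0.0206059
110.53,9.00014e-05,0.14473,0.00227376,0.0215251
122.168,5.43442e-05,0.141121,0.00173415,0.0224424
135.031,3.28139e-05,0.13742,0.00139122,0.0233406
149.25,1.98135e-05,0.133642,0.00123356,0.0242064
164.965,1.19637e-05,0.129799,0.00086812,0.0250291
182.335,7.22387e-06,0.125908,0.000660896,0.0258002
201.534,4.36189e-06,0.121982,0.000584356,0.0265128
222.754,2.63377e-06,0.118038,0.000299196,0.0271614
246.209,1.59031e-06,0.114088,0.000164423,0.0277414
272.134,9.60256e-07,0.110147,0.000161946,0.0282494
300.788,5.79817e-07,0.106226,0.000265682,0.028683
332.46,3.50102e-07,0.102337,0.000142125,0.0290405
367.466,2.11397e-07,0.0984894,0.000128547,0.0293207
406.159,1.27645e-07,0.0946909,0.000175545,0.0295232
448.925,7.7074e-08,0.0909486,0.000119605,0.0296479
496.195,4.65384e-08,0.0872684,0.000153696,0.0296952
548.442,2.81006e-08,0.0836548,9.8507e-05,0.0296656
606.19,1.69676e-08,0.0801116,9.56306e-05,0.0295603
670.019,1.02453e-08,0.0766417,1.9042e-05,0.0293806
740.568,6.18626e-09,0.0732475,2.35567e-05,0.0291282
818.547,3.73536e-09,0.0699309,5.90942e-05,0.0288054
904.736,2.25547e-09,0.0666939,2.98951e-05,0.0284148
1000,1.36189e-09,0.0635379,7.20616e-05,0.0279594
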