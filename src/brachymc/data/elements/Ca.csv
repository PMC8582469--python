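# Element photon interaction data: Ca (Z=20)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Anchored element (totals transcribed, E>=10 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=20 A=40.078 k_edge_keV=4.038 k_yield=0.163 k_photo_fraction=0.88
# k_lines_keV=3.69 k_line_weights=1
E_keV,pe,compton,rayleigh,mu_en
1,9285.08,0.199142,3.58149,9285.08
1.1053,6929.29,0.19906,3.51015,6929.29
1.22168,5171.2,0.19897,3.43024,5171.2
1.35031,3859.17,0.198871,3.34178,3859.17
1.4925,2880.03,0.198761,3.24505,2880.03
1.64965,2149.31,0.19864,3.14054,2149.31
1.82335,1603.99,0.198507,3.029,1603.99
2.01534,1197.03,0.198359,2.9113,1197.03
2.22754,893.321,0.198197,2.78841,893.322
2.46209,666.669,0.198018,2.6613,666.67
2.72134,497.523,0.19782,2.5309,497.524
3.00788,371.292,0.197602,2.39804,371.293
3.3246,277.089,0.197362,2.26345,277.09
3.67466,206.786,0.197098,2.12778,206.788
4.0378,156.993,0.196825,1.99964,156.995
4.0382,1307.9,0.196824,1.99951,1136.47
4.06159,1286.01,0.196807,1.99165,1118.42
4.48925,959.723,0.196486,1.85568,846.571
4.96195,716.223,0.196133,1.72055,639.825
5.48442,534.504,0.195746,1.58704,482.922
6.0619,398.891,0.195319,1.45604,364.064
6.70019,297.685,0.194851,1.32852,274.171
7.40568,222.157,0.194336,1.20548,206.282
8.18547,165.791,0.193772,1.08788,155.074
9.04736,123.727,0.193153,0.976574,116.492
10,92.3353,0.192475,0.872247,87.4516
11.053,68.9081,0.191733,0.837369,65.6123
12.2168,51.4249,0.190921,0.752685,49.2012
13.5031,38.3774,0.190034,0.645654,36.8779
14.925,28.6404,0.189067,0.533053,27.6299
16.4965,21.5213,0.188013,0.486863,20.8365
18.2335,16.1777,0.186866,0.422769,15.7142
20.1534,12.1482,0.185619,0.356423,11.8358
22.2754,9.00778,0.184267,0.343514,8.80108
24.6209,6.67922,0.182803,0.303116,6.5436
27.2134,4.9526,0.18122,0.250149,4.86492
30.0788,3.67157,0.179513,0.195249,3.61633
33.246,2.70127,0.177676,0.183265,2.66838
36.7466,1.98739,0.175704,0.154342,1.96969
40.6159,1.46107,0.173591,0.123426,1.45379
44.8925,1.06965,0.171336,0.11096,1.06968
49.6195,0.783095,0.168934,0.0876035,0.78829
54.8442,0.571801,0.166384,0.0779574,0.58077
60.619,0.417232,0.163687,0.0632401,0.429041
67.0019,0.303199,0.160843,0.061036,0.31724
74.0568,0.220332,0.157855,0.0498233,0.236191
81.8547,0.159326,0.154727,0.0381381,0.176734
90.4736,0.113313,0.151467,0.0343722,0.132091
100,0.0805883,0.148081,0.0254304,0.100597
110.53,0.0487302,0.14458,0.031988,0.0699098
122.168,0.0294663,0.140975,0.0293202,0.0517036
135.031,0.0178177,0.137279,0.0220233,0.0410316
149.25,0.010774,0.133504,0.0127659,0.0348974
164.965,0.0102044,0.129665,0.00593966,0.0351629
182.335,0.00989631,0.125778,3.37043e-05,0.035634
201.534,0.00939101,0.117083,1e-08,0.0348102
222.754,0.00684855,0.112933,1e-08,0.0328165
246.209,0.00499441,0.108449,1e-08,0.0313522
272.134,0.00364225,0.103798,1e-08,0.0302553
300.788,0.00265617,0.0991171,1e-08,0.0294143
332.46,0.00193705,0.0951194,1e-08,0.0289259
367.466,0.00141263,0.0911455,1e-08,0.0285448
406.159,0.00103018,0.0872521,1e-08,0.0282327
448.925,0.000751276,0.0835263,1e-08,0.0279787
496.195,0.00054788,0.0799066,1e-08,0.0277374
548.442,0.00039955,0.0764156,1e-08,0.0274976
606.19,0.000291378,0.0730423,1e-08,0.0272429
670.019,0.000212492,0.0697352,1e-08,0.0269453
740.568,0.000154963,0.0665631,1e-08,0.0266249
818.547,0.000113009,0.0635046,1e-08,0.0262713
904.736,8.24139e-05,0.0605147,1e-08,0.0258645
1000,6.01017e-05,0.0576599,1e-08,0.0254329
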