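# Element photon interaction data: Cr (Z=24)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel log-log interpolated in Z between anchor elements (approximate below ~25 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=24 A=51.996 k_edge_keV=5.989 k_yield=0.282 k_photo_fraction=0.87
# k_lines_keV=5.41 k_line_weights=1
E_keV,pe,compton,rayleigh,mu_en
1,9889.75,0.184196,4.01875,9889.75
1.1053,7501.51,0.18412,3.94524,7501.51
1.22168,5690,0.184037,3.86233,5690
1.35031,4315.94,0.183945,3.76989,4315.94
1.4925,3273.7,0.183844,3.66805,3273.7
1.64965,2483.15,0.183732,3.55721,2483.15
1.82335,1883.5,0.183608,3.43804,1883.5
2.01534,1428.66,0.183472,3.31142,1428.66
2.22754,1083.66,0.183322,3.17839,1083.66
2.46209,821.971,0.183156,3.04002,821.972
2.72134,623.476,0.182973,2.89738,623.477
3.00788,472.915,0.182772,2.75147,472.916
3.3246,358.713,0.18255,2.60316,358.714
3.67466,272.089,0.182305,2.45322,272.09
4.06159,206.383,0.182036,2.30236,206.384
4.48925,156.544,0.181739,2.15125,156.546
4.96195,118.741,0.181413,2.00059,118.743
5.48442,248.753,0.181054,1.8512,248.754
5.9887,195.118,0.18071,1.7217,195.12
5.9893,195.064,0.180709,1.72156,151.838
6.0619,188.682,0.18066,1.70399,147.371
6.70019,143.118,0.180227,1.55997,114.769
7.40568,314.172,0.179751,1.42025,257.867
8.18547,238.304,0.179229,1.28594,199.665
9.04736,180.757,0.178656,1.15805,154.242
10,137.106,0.178029,1.03748,118.912
11.053,103.997,0.177343,0.924881,91.5123
12.2168,78.8832,0.176592,0.820696,70.317
13.5031,59.834,0.175772,0.725109,53.957
14.925,45.3849,0.174877,0.638081,41.3536
16.4965,34.1365,0.173902,0.559391,31.3951
18.2335,25.6645,0.172841,0.488673,23.802
20.1534,19.2835,0.171688,0.425462,18.0197
22.2754,14.3839,0.170438,0.36923,13.5336
24.6209,10.7293,0.169083,0.319425,10.1582
27.2134,8.00315,0.167619,0.275486,7.62081
30.0788,5.96859,0.16604,0.236869,5.71387
33.246,4.42032,0.164341,0.203053,4.25321
36.7466,3.27367,0.162517,0.173547,3.16553
40.6159,2.4227,0.160563,0.147898,2.3544
44.8925,1.78565,0.158477,0.125682,1.74454
49.6195,1.31611,0.156255,0.106514,1.29343
54.8442,0.96723,0.153897,0.0900371,0.957222
60.619,0.710386,0.151402,0.0759265,0.709124
67.0019,0.519962,0.148771,0.0638865,0.524864
74.0568,0.380582,0.146007,0.0536494,0.389887
81.8547,0.278289,0.143115,0.0449749,0.290831
90.4736,0.202815,0.140099,0.0376481,0.217822
100,0.14781,0.136967,0.0314787,0.16475
110.53,0.107169,0.133729,0.0262992,0.125688
122.168,0.0777019,0.130395,0.0219632,0.0975442
135.031,0.0563372,0.126976,0.0183431,0.0773197
149.25,0.0408468,0.123484,0.0153288,0.0628318
164.965,0.0293558,0.119934,0.0128255,0.0522352
182.335,0.0210876,0.116338,0.0107521,0.0447666
201.534,0.0151112,0.112711,0.00903924,0.0395054
222.754,0.0105134,0.109066,0.00762826,0.0355452
246.209,0.0073145,0.105417,0.00646945,0.0329065
272.134,0.00508894,0.101775,0.00552085,0.0311655
300.788,0.00354621,0.0981526,0.00474714,0.030033
332.46,0.00262218,0.0945591,0.0041186,0.0294446
367.466,0.00193892,0.0910037,0.00361021,0.0290239
406.159,0.00146522,0.0874938,0.0032009,0.0287396
448.925,0.00124931,0.084036,0.00287293,0.0286401
496.195,0.00106522,0.0806355,0.00261138,0.0285005
548.442,0.000791127,0.0772966,0.00240377,0.0282
606.19,0.000580897,0.0740227,0.00223968,0.0278931
670.019,0.000426533,0.0708165,0.00211049,0.0275732
740.568,0.000313189,0.0676802,0.00200913,0.0272269
818.547,0.000229964,0.0646158,0.00192986,0.0268456
904.736,0.000168854,0.0616248,0.00186803,0.0264237
1000,0.000123984,0.0587087,0.00181995,0.0259581
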