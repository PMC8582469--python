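# Element photon interaction data: Ir (Z=77)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel scaled from the lead anchor (Z-power law, own K edge; approximate).
# Regenerate with tools/make_physics_tables.py.
# Z=77 A=192.217 k_edge_keV=76.111 k_yield=0.958 k_photo_fraction=0.8
# k_lines_keV=63.287,64.896,73.36 k_line_weights=0.29,0.5,0.21
E_keV,pe,compton,rayleigh,mu_en
1,21706.7,0.159859,11.7622,21706.7
1.1053,17242.3,0.159794,11.6451,17242.3
1.22168,13696,0.159721,11.5083,13696
1.35031,10879.1,0.159642,11.3495,10879.1
1.4925,8641.61,0.159554,11.167,8641.61
1.64965,6864.27,0.159457,10.9593,6864.27
1.82335,5452.49,0.159349,10.7253,5452.49
2.01534,4331.06,0.159231,10.4648,4331.06
2.22754,3440.29,0.159101,10.1781,3440.29
2.46209,2732.72,0.158957,9.86665,2732.72
2.72134,2170.67,0.158798,9.53224,2170.67
3.00788,1724.23,0.158623,9.17741,1724.23
3.3246,1369.6,0.158431,8.80506,1369.6
3.67466,1087.91,0.158218,8.41823,1087.92
4.06159,864.161,0.157985,8.01985,864.162
4.48925,686.427,0.157727,7.61265,686.429
4.96195,545.249,0.157444,7.19904,545.25
5.48442,433.106,0.157133,6.78115,433.108
6.0619,344.029,0.15679,6.3609,344.03
6.70019,273.272,0.156414,5.94018,273.274
7.40568,217.067,0.156001,5.52099,217.07
8.18547,172.423,0.155548,5.1056,172.425
9.04736,136.96,0.155052,4.69659,136.963
10,108.791,0.154507,4.29685,108.794
11.053,104.856,0.153911,3.90944,104.86
12.2168,101.064,0.15326,3.53742,101.067
13.5031,97.4082,0.152548,3.18362,97.412
14.925,93.8849,0.151772,2.85044,93.889
16.4965,86.1515,0.150926,2.53965,86.156
18.2335,78.8505,0.150005,2.25238,78.8555
20.1534,71.2113,0.149004,1.98906,71.2167
22.2754,54.7168,0.147919,1.74953,54.7227
24.6209,42.0429,0.146743,1.53311,42.0493
27.2134,32.3046,0.145473,1.33875,32.3115
30.0788,24.819,0.144102,1.16513,24.8265
33.246,18.9847,0.142628,1.01076,18.9928
36.7466,14.5218,0.141044,0.874094,14.5306
40.6159,11.1024,0.139349,0.753584,11.1119
44.8925,8.46412,0.137538,0.647716,8.47426
49.6195,6.45276,0.13561,0.555048,6.46363
54.8442,4.91016,0.133563,0.474229,4.92179
60.619,3.73519,0.131398,0.404002,3.7476
67.0019,2.8376,0.129115,0.343205,2.85079
74.0568,2.1557,0.126716,0.290771,2.16969
76.1072,1.99995,0.126042,0.277788,2.01417
76.1148,9.52097,0.12604,0.277741,3.18816
81.8547,7.79794,0.124206,0.245718,2.97887
90.4736,5.89032,0.121588,0.207153,2.60242
100,4.53135,0.118871,0.174261,2.2485
110.53,3.48763,0.11606,0.146306,1.90375
122.168,2.68432,0.113167,0.122627,1.58737
135.031,2.06604,0.110199,0.102634,1.30837
149.25,1.59016,0.107169,0.0858055,1.06894
164.965,1.21948,0.104087,0.0716822,0.864444
182.335,0.935024,0.100967,0.0598626,0.695505
201.534,0.717072,0.0978191,0.0499978,0.55779
222.754,0.551323,0.0946559,0.0417864,0.447517
246.209,0.423886,0.0914888,0.0349691,0.358773
272.134,0.325906,0.0883283,0.0293242,0.287792
300.788,0.250622,0.0851843,0.0246625,0.231344
332.46,0.194102,0.0820656,0.0208238,0.187765
367.466,0.150328,0.0789799,0.0176722,0.153083
406.159,0.116544,0.0759338,0.0150934,0.125659
448.925,0.0908595,0.0729328,0.012991,0.104365
496.195,0.0708357,0.0699816,0.011284,0.0874049
548.442,0.0554276,0.0670838,0.00990394,0.0740888
606.19,0.043386,0.0642425,0.0087935,0.0634592
670.019,0.0339725,0.0614599,0.00790424,0.0549604
740.568,0.0266015,0.058738,0.00719548,0.0481372
818.547,0.0207855,0.0560785,0.00663318,0.0425964
904.736,0.0161251,0.0534827,0.00618895,0.0380069
1000,0.0125096,0.0509518,0.00583936,0.0342958
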