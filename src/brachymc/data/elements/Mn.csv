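# Element photon interaction data: Mn (Z=25)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel log-log interpolated in Z between anchor elements (approximate below ~25 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=25 A=54.938 k_edge_keV=6.539 k_yield=0.314 k_photo_fraction=0.87
# k_lines_keV=5.9 k_line_weights=1
E_keV,pe,compton,rayleigh,mu_en
1,10500.9,0.181596,4.13664,10500.9
1.1053,7981.88,0.181521,4.06243,7981.88
1.22168,6067.12,0.181439,3.97862,6067.12
1.35031,4611.69,0.181349,3.88502,4611.69
1.4925,3505.4,0.181249,3.78172,3505.4
1.64965,2664.5,0.181138,3.66911,2664.5
1.82335,2025.31,0.181017,3.54784,2025.31
2.01534,1539.46,0.180882,3.41879,1539.47
2.22754,1170.16,0.180734,3.283,1170.17
2.46209,889.456,0.180571,3.14158,889.457
2.72134,676.086,0.18039,2.99563,676.087
3.00788,513.901,0.180192,2.84619,513.902
3.3246,390.622,0.179973,2.69416,390.623
3.67466,296.916,0.179732,2.54037,296.918
4.06159,225.69,0.179466,2.38553,225.691
4.48925,171.549,0.179174,2.23033,171.551
4.96195,130.397,0.178852,2.07551,130.398
5.48442,163.054,0.178499,1.92186,163.056
6.0619,123.939,0.17811,1.77031,123.941
6.53867,100.721,0.17779,1.65773,100.724
6.53933,100.694,0.17779,1.65758,75.8778
6.70019,94.2078,0.177683,1.6219,71.5479
7.40568,341.188,0.177214,1.47775,266.935
8.18547,259.341,0.176699,1.33899,208.278
9.04736,197.128,0.176134,1.20671,162.013
10,149.839,0.175516,1.08181,125.692
11.053,113.895,0.174839,0.965035,97.2899
12.2168,86.5726,0.174099,0.856851,75.155
13.5031,65.8049,0.173291,0.757483,57.9546
14.925,50.0191,0.172409,0.666924,44.6222
16.4965,37.6938,0.171447,0.584968,34.0161
18.2335,28.3927,0.170401,0.511256,25.8885
20.1534,21.3735,0.169265,0.445323,19.6703
22.2754,15.9705,0.168032,0.386635,14.8216
24.6209,11.9333,0.166696,0.334623,11.1594
27.2134,8.91669,0.165253,0.288714,8.39647
30.0788,6.66136,0.163696,0.248345,6.31295
33.246,4.94116,0.162021,0.212977,4.71084
36.7466,3.66517,0.160223,0.182103,3.51437
40.6159,2.71671,0.158297,0.155249,2.61963
44.8925,2.00558,0.15624,0.13198,1.9451
49.6195,1.48059,0.154049,0.111891,1.44485
54.8442,1.08973,0.151725,0.0946149,1.07092
60.619,0.801545,0.149265,0.079812,0.794324
67.0019,0.587594,0.146671,0.0671751,0.588447
74.0568,0.430751,0.143946,0.0564255,0.437275
81.8547,0.315482,0.141094,0.0473124,0.326084
90.4736,0.230341,0.138121,0.039612,0.243966
100,0.168178,0.135034,0.0331253,0.184103
110.53,0.122196,0.131842,0.0276773,0.13994
122.168,0.088786,0.128554,0.0231147,0.108009
135.031,0.0645107,0.125183,0.0193041,0.084973
149.25,0.0468726,0.121741,0.01613,0.0683992
164.965,0.0338088,0.118241,0.0134931,0.0562678
182.335,0.0243766,0.114696,0.0113082,0.0476573
201.534,0.0175419,0.11112,0.0095026,0.0415495
222.754,0.0123316,0.107527,0.00801464,0.0369826
246.209,0.00866883,0.103929,0.00679208,0.0338816
272.134,0.006094,0.100339,0.00579083,0.0317909
300.788,0.00428193,0.0967671,0.00497376,0.0303873
332.46,0.00295664,0.0932243,0.00430961,0.0293965
367.466,0.00204154,0.0897191,0.0037721,0.0287422
406.159,0.0014718,0.0862588,0.00333906,0.0283601
448.925,0.00134817,0.0828498,0.00299185,0.0283511
496.195,0.00123492,0.0794973,0.00271479,0.0282817
548.442,0.000923504,0.0762055,0.00249472,0.0279447
606.19,0.000679145,0.0729778,0.00232069,0.0276053
670.019,0.000499443,0.0698168,0.0021836,0.0272625
740.568,0.000367291,0.0667248,0.002076,0.0269009
818.547,0.000270105,0.0637037,0.00199181,0.0265099
904.736,0.000198635,0.0607549,0.00192613,0.0260828
1000,0.000146077,0.05788,0.00187502,0.0256155
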