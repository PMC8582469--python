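# Element photon interaction data: Ar (Z=18)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Anchored element (totals transcribed, E>=10 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=18 A=39.948 k_edge_keV=3.203 k_yield=0.0 k_photo_fraction=0.0
E_keV,pe,compton,rayleigh,mu_en
1,50587.5,0.179811,2.89089,50587.5
1.1053,37791.2,0.179737,2.83049,37791.2
1.22168,28231.7,0.179656,2.7631,28231.7
1.35031,21090.4,0.179566,2.68882,21090.4
1.4925,15755.5,0.179467,2.60794,15755.5
1.64965,11770.1,0.179358,2.52093,11770.1
1.82335,8792.79,0.179237,2.42845,8792.79
2.01534,6568.61,0.179104,2.33123,6568.61
2.22754,4907.05,0.178958,2.23007,4907.06
2.46209,3665.79,0.178796,2.12576,3665.79
2.72134,2738.52,0.178617,2.01902,2738.52
3.00788,2045.8,0.178421,1.91049,2045.8
3.3246,1528.3,0.178204,1.80076,1528.3
3.67466,1141.71,0.177965,1.69032,1141.71
4.06159,852.911,0.177702,1.57968,852.913
4.48925,637.164,0.177413,1.46936,637.165
4.96195,475.991,0.177095,1.35993,475.992
5.48442,355.587,0.176744,1.25207,355.589
6.0619,265.64,0.176359,1.14651,265.642
6.70019,198.445,0.175936,1.04407,198.447
7.40568,148.247,0.175472,0.945548,148.25
8.18547,110.748,0.174962,0.851704,110.75
9.04736,82.7335,0.174403,0.763189,82.7365
10,61.8057,0.173791,0.680499,61.809
11.053,46.1717,0.173121,0.654747,46.1753
12.2168,34.4924,0.172388,0.588336,34.4963
13.5031,25.7674,0.171588,0.50342,25.7717
14.925,19.2494,0.170714,0.41359,19.2541
16.4965,14.3689,0.169762,0.380211,14.374
18.2335,10.7253,0.168727,0.329536,10.7309
20.1534,7.9983,0.167601,0.276071,8.00439
22.2754,5.89843,0.16638,0.270036,5.90505
24.6209,4.34986,0.165058,0.238745,4.35705
27.2134,3.20785,0.163629,0.195664,3.21565
30.0788,2.36527,0.162088,0.150361,2.37372
33.246,1.73325,0.160429,0.142705,1.74239
36.7466,1.27011,0.158648,0.119895,1.27998
40.6159,0.930105,0.156741,0.0949301,0.940726
44.8925,0.678574,0.154704,0.0858041,0.689986
49.6195,0.495065,0.152535,0.0671812,0.507298
54.8442,0.359982,0.150233,0.0599826,0.373064
60.619,0.261561,0.147798,0.0483922,0.275514
67.0019,0.189259,0.145229,0.0468747,0.2041
74.0568,0.136943,0.142531,0.0382482,0.152685
81.8547,0.0989526,0.139708,0.0289429,0.115601
90.4736,0.0711727,0.136764,0.0258826,0.0887269
100,0.0511917,0.133707,0.0194015,0.0696436
110.53,0.0364605,0.130546,0.0199711,0.0557949
122.168,0.0259684,0.127291,0.0178645,0.0461624
135.031,0.0184956,0.123953,0.0141657,0.0395192
149.25,0.0131732,0.120544,0.00961728,0.0349894
164.965,0.00913451,0.117078,0.00872954,0.0316999
182.335,0.00632507,0.113568,0.00733753,0.0295903
201.534,0.00433332,0.110028,0.00570569,0.0282439
222.754,0.00260978,0.10647,0.00545094,0.0271069
246.209,0.00157177,0.102907,0.00477044,0.026593
272.134,0.00094661,0.0993524,0.00391308,0.0264266
300.788,0.000578171,0.095816,0.00302162,0.0264497
332.46,0.000595141,0.0923081,0.00225251,0.0267893
367.466,0.000612609,0.0888372,0.00162833,0.0270597
406.159,0.000597909,0.0854109,0.00116517,0.0272277
448.925,0.000434277,0.0820355,0.000960394,0.0271766
496.195,0.000315426,0.0787159,0.000815686,0.0271004
548.442,0.000229102,0.0754565,0.000671143,0.0269874
606.19,0.000166402,0.0722605,0.000574864,0.0268297
670.019,0.000120862,0.0691306,0.000438914,0.0266221
740.568,8.77853e-05,0.066069,0.000372413,0.0263614
818.547,6.37606e-05,0.0630775,0.000340743,0.0260462
904.736,4.6311e-05,0.0601577,0.000275985,0.0256764
1000,3.36368e-05,0.0573111,0.000275297,0.0252529
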