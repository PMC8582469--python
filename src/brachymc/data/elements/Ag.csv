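# Element photon interaction data: Ag (Z=47)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Anchored element with K-edge duplicate points.
# Regenerate with tools/make_physics_tables.py.
# Z=47 A=107.868 k_edge_keV=25.514 k_yield=0.831 k_photo_fraction=0.825
# k_lines_keV=21.99,22.163,24.93 k_line_weights=0.286,0.543,0.171
E_keV,pe,compton,rayleigh,mu_en
1,34558.9,0.173878,7.67451,34558.9
1.1053,26291.7,0.173807,7.57444,26291.7
1.22168,20002.2,0.173728,7.45902,20002.2
1.35031,15217.2,0.173641,7.32716,15217.2
1.4925,11577,0.173545,7.17807,11577
1.64965,8807.52,0.17344,7.01138,8807.52
1.82335,6700.58,0.173323,6.82719,6700.58
2.01534,5097.66,0.173195,6.62614,5097.67
2.22754,3878.2,0.173053,6.40937,3878.2
2.46209,2950.45,0.172896,6.17841,2950.46
2.72134,2244.65,0.172724,5.93512,2244.65
3.00788,1707.68,0.172533,5.68149,1707.68
3.3246,1299.17,0.172324,5.41951,1299.17
3.67466,988.381,0.172093,5.15106,988.382
4.06159,751.94,0.171839,4.8778,751.941
4.48925,572.06,0.171559,4.60122,572.062
4.96195,435.212,0.171251,4.32262,435.214
5.48442,331.1,0.170912,4.04327,331.102
6.0619,251.894,0.17054,3.76444,251.896
6.70019,191.636,0.170131,3.48757,191.638
7.40568,145.793,0.169682,3.2143,145.795
8.18547,110.916,0.169189,2.94648,110.919
9.04736,84.3828,0.168648,2.68612,84.3856
10,64.1967,0.168056,2.43526,64.1998
11.053,48.8395,0.167408,2.29331,48.843
12.2168,37.1561,0.1667,2.07412,37.1599
13.5031,28.2676,0.165926,1.82203,28.2718
14.925,21.5054,0.165081,1.5648,21.51
16.4965,16.065,0.164161,1.42152,16.0699
18.2335,11.9893,0.163159,1.24812,11.9947
20.1534,8.95509,0.162071,1.07011,8.96097
22.2754,6.75673,0.16089,0.951285,6.76313
24.6209,5.09803,0.159612,0.82049,5.10499
25.5127,4.61237,0.159132,0.773649,4.61954
25.5153,29.5664,0.159131,0.773541,11.6301
27.2134,24.4651,0.15823,0.714454,10.5516
30.0788,18.2382,0.156739,0.612172,8.85717
33.246,13.8708,0.155135,0.544089,7.41908
36.7466,10.5492,0.153413,0.466096,6.11338
40.6159,8.01411,0.151569,0.392141,4.96899
44.8925,6.05048,0.149599,0.341569,3.97451
49.6195,4.56798,0.147502,0.284991,3.15427
54.8442,3.43081,0.145276,0.246655,2.4748
60.619,2.57488,0.142921,0.206817,1.93063
67.0019,1.92754,0.140437,0.184252,1.49642
74.0568,1.44295,0.137828,0.153654,1.15646
81.8547,1.07928,0.135098,0.125452,0.891206
90.4736,0.804977,0.132251,0.108638,0.684178
100,0.60039,0.129295,0.0867155,0.525263
110.53,0.430103,0.126238,0.0884346,0.388543
122.168,0.308114,0.12309,0.0780258,0.288588
135.031,0.220725,0.119863,0.0615922,0.215743
149.25,0.158122,0.116567,0.0429452,0.162813
164.965,0.112921,0.113215,0.0401319,0.124142
182.335,0.0806286,0.109821,0.0334629,0.0962787
201.534,0.0575472,0.106397,0.0251958,0.0762472
222.754,0.0408698,0.102957,0.0248512,0.0617175
246.209,0.0290256,0.0995117,0.0218914,0.0513957
272.134,0.0206139,0.0960741,0.0174663,0.0440802
300.788,0.0146232,0.0926544,0.0124785,0.0388882
332.46,0.00994333,0.0892622,0.0116071,0.03481
367.466,0.00676116,0.0859059,0.00986996,0.0320506
406.159,0.00495411,0.0825926,0.00751469,0.0305163
448.925,0.00549681,0.0793285,0.00424848,0.0311671
496.195,0.00609896,0.0761185,0.00124586,0.0318097
548.442,0.00471925,0.0729666,0.00105057,0.0304613
606.19,0.00354452,0.0698761,0.000924388,0.0292375
670.019,0.00266221,0.0668495,0.000904273,0.0282274
740.568,0.00199953,0.0638889,0.000806136,0.0273644
818.547,0.0015018,0.0609962,0.000657085,0.0265985
904.736,0.00112797,0.0581727,0.000455374,0.025893
1000,0.000847195,0.05542,0.000272838,0.0252212
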