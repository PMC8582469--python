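# Element photon interaction data: Si (Z=14)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel log-log interpolated in Z between anchor elements (approximate below ~25 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=14 A=28.085 k_edge_keV=1.839 k_yield=0.0 k_photo_fraction=0.0
E_keV,pe,compton,rayleigh,mu_en
1,25734,0.198926,2.44442,25734
1.1053,19364.7,0.198845,2.38742,19364.7
1.22168,14571.9,0.198755,2.32446,14571.9
1.35031,10965.3,0.198656,2.25577,10965.3
1.4925,8251.39,0.198546,2.18173,8251.39
1.64965,6189.17,0.198425,2.10287,6189.17
1.82335,4641.56,0.198292,2.01984,4641.56
2.01534,3480.21,0.198145,1.9333,3480.21
2.22754,2602.89,0.197982,1.84394,2602.89
2.46209,1946.73,0.197803,1.7524,1946.73
2.72134,1455.98,0.197606,1.65923,1455.98
3.00788,1088.87,0.197388,1.56495,1088.87
3.3246,812.36,0.197149,1.46999,812.362
3.67466,606.066,0.196885,1.37479,606.068
4.06159,452.051,0.196594,1.27978,452.053
4.48925,336.727,0.196273,1.18546,336.729
4.96195,250.824,0.195921,1.09239,250.826
5.48442,186.641,0.195534,1.00119,186.643
6.0619,138.853,0.195108,0.912558,138.855
6.70019,103.191,0.19464,0.827187,103.193
7.40568,76.6879,0.194126,0.74574,76.6906
8.18547,56.9757,0.193562,0.668794,56.9787
9.04736,42.2902,0.192944,0.596801,42.2935
10,31.3899,0.192266,0.530064,31.3935
11.053,23.2661,0.191525,0.46873,23.27
12.2168,17.2447,0.190714,0.412805,17.2491
13.5031,12.7817,0.189829,0.362169,12.7865
14.925,9.47377,0.188862,0.316609,9.47895
16.4965,7.00841,0.187809,0.275842,7.01408
18.2335,5.18409,0.186664,0.239542,5.19027
20.1534,3.83187,0.185418,0.207363,3.8386
22.2754,2.80763,0.184068,0.178952,2.81495
24.6209,2.05716,0.182605,0.153962,2.06512
27.2134,1.50729,0.181024,0.132063,1.51593
30.0788,1.10424,0.179319,0.112942,1.1136
33.246,0.80477,0.177484,0.0963065,0.814883
36.7466,0.586516,0.175513,0.0818875,0.597427
40.6159,0.42722,0.173404,0.0694366,0.43897
44.8925,0.310251,0.17115,0.0587255,0.322876
49.6195,0.225307,0.168751,0.0495457,0.238841
54.8442,0.16321,0.166204,0.0417071,0.177682
60.619,0.118162,0.16351,0.0350376,0.133598
67.0019,0.0852864,0.160669,0.0293822,0.101705
74.0568,0.0615577,0.157684,0.0246024,0.078973
81.8547,0.0443967,0.15456,0.0205751,0.062815
90.4736,0.031937,0.151303,0.017192,0.0513574
100,0.022974,0.147921,0.0143581,0.0433876
110.53,0.016409,0.144424,0.0119909,0.0377987
122.168,0.0117199,0.140823,0.0100188,0.0340607
135.031,0.00837084,0.13713,0.00838008,0.0316294
149.25,0.00597878,0.133359,0.00702202,0.0301142
164.965,0.00419209,0.129525,0.00589953,0.0291563
182.335,0.00293647,0.125642,0.00497431,0.028675
201.534,0.00204188,0.121725,0.00421396,0.0284943
222.754,0.00129899,0.117788,0.0035911,0.0284003
246.209,0.00082639,0.113847,0.00308269,0.0285076
272.134,0.00052573,0.109914,0.00266932,0.0287145
300.788,0.000337716,0.106002,0.00233465,0.0289596
332.46,0.000311006,0.102121,0.00206495,0.0292898
367.466,0.000286408,0.0982814,0.00184863,0.029545
406.159,0.000254246,0.0944908,0.00167596,0.029715
448.925,0.000184064,0.0907565,0.00153876,0.0297693
496.195,0.000133255,0.0870841,0.00143023,0.0297656
548.442,9.64715e-05,0.0834781,0.00134472,0.0296994
606.19,6.98416e-05,0.0799424,0.00127759,0.0295677
670.019,5.05626e-05,0.0764798,0.00122505,0.0293691
740.568,3.66053e-05,0.0730927,0.00118405,0.0291033
818.547,2.65008e-05,0.0697832,0.00115215,0.0287711
904.736,1.91856e-05,0.066553,0.00112739,0.028374
1000,1.38896e-05,0.0634037,0.00110824,0.0279142
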