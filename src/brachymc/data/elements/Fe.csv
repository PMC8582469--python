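# Element photon interaction data: Fe (Z=26)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Anchored element (totals transcribed, E>=10 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=26 A=55.845 k_edge_keV=7.112 k_yield=0.347 k_photo_fraction=0.87
# k_lines_keV=6.4 k_line_weights=1
E_keV,pe,compton,rayleigh,mu_en
1,11537.3,0.185792,4.4111,11537.3
1.1053,8787.36,0.185716,4.33345,8787.36
1.22168,6692.9,0.185632,4.24562,6692.9
1.35031,5097.64,0.18554,4.14738,5097.64
1.4925,3882.62,0.185437,4.0388,3882.62
1.64965,2957.2,0.185324,3.92024,2957.2
1.82335,2252.35,0.1852,3.79236,2252.35
2.01534,1715.5,0.185062,3.65607,1715.5
2.22754,1306.61,0.184911,3.51246,1306.61
2.46209,995.181,0.184743,3.36269,995.182
2.72134,757.98,0.184559,3.20797,757.981
3.00788,577.315,0.184356,3.04938,577.316
3.3246,439.712,0.184132,2.88793,439.713
3.67466,334.907,0.183885,2.72449,334.908
4.06159,255.082,0.183614,2.55983,255.083
4.48925,194.283,0.183315,2.39471,194.285
4.96195,147.976,0.182986,2.22987,147.977
5.48442,112.706,0.182624,2.06617,112.708
6.0619,85.8423,0.182226,1.90456,85.8444
6.70019,65.3818,0.181789,1.74615,65.3841
7.11164,55.5987,0.181508,1.65384,55.6011
7.11236,427.566,0.181508,1.65369,311.418
7.40568,383.062,0.181309,1.59211,283.126
8.18547,291.759,0.180782,1.44365,222.895
9.04736,222.218,0.180205,1.30193,174.766
10,169.252,0.179572,1.16796,136.555
11.053,128.911,0.17888,1.0994,106.381
12.2168,98.1852,0.178123,0.987742,82.6611
13.5031,74.7827,0.177295,0.857403,64.0869
14.925,56.9583,0.176393,0.723649,49.5896
16.4965,43.0017,0.175409,0.657334,37.9706
18.2335,32.4499,0.174339,0.572846,29.0171
20.1534,24.4719,0.173176,0.487069,22.1321
22.2754,18.316,0.171915,0.457427,16.7342
24.6209,13.7087,0.170549,0.402386,12.6403
27.2134,10.2603,0.169072,0.336559,9.53988
30.0788,7.67782,0.167479,0.270355,7.19337
33.246,5.70375,0.165765,0.247877,5.38172
36.7466,4.23724,0.163925,0.209984,4.02464
40.6159,3.14551,0.161955,0.1714,3.00686
44.8925,2.32573,0.15985,0.152041,2.23743
49.6195,1.7196,0.157609,0.122593,1.66528
54.8442,1.26745,0.155231,0.107993,1.23632
60.619,0.933594,0.152714,0.0887469,0.918254
67.0019,0.685415,0.15006,0.0838272,0.680985
74.0568,0.50321,0.147273,0.0687326,0.506347
81.8547,0.369122,0.144355,0.0536262,0.377612
90.4736,0.269978,0.141313,0.0478296,0.282351
100,0.197464,0.138155,0.0360813,0.212715
110.53,0.143769,0.134888,0.0388744,0.161233
122.168,0.104674,0.131525,0.0350577,0.123884
135.031,0.0762105,0.128076,0.0274394,0.0968429
149.25,0.0554869,0.124554,0.0179149,0.0773105
164.965,0.0401619,0.120973,0.0169261,0.0630075
182.335,0.0290606,0.117346,0.0141952,0.0527918
201.534,0.0209975,0.113688,0.0105356,0.0455021
222.754,0.0149084,0.110011,0.0104654,0.0400911
246.209,0.0105851,0.106331,0.00930025,0.0363556
272.134,0.00751554,0.102657,0.00749467,0.0337898
300.788,0.00532302,0.0990033,0.00541712,0.0320209
332.46,0.00344147,0.0953787,0.00511446,0.030487
367.466,0.002225,0.0917924,0.00441585,0.0295401
406.159,0.00153311,0.0882521,0.00350425,0.0290414
448.925,0.00150443,0.0847643,0.00249615,0.0291298
496.195,0.00147629,0.0813344,0.00164916,0.0291465
548.442,0.00111135,0.0779665,0.00138286,0.0287558
606.19,0.000818498,0.0746642,0.00117406,0.0283661
670.019,0.000602817,0.0714302,0.000984116,0.0279838
740.568,0.000443969,0.0682668,0.000839584,0.0275904
818.547,0.000326979,0.0651758,0.000727605,0.0271729
904.736,0.000240818,0.0621589,0.000612301,0.026723
1000,0.00017736,0.0592175,0.000555139,0.0262352
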