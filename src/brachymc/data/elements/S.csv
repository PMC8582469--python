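# Element photon interaction data: S (Z=16)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel log-log interpolated in Z between anchor elements (approximate below ~25 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=16 A=32.06 k_edge_keV=2.472 k_yield=0.0 k_photo_fraction=0.0
E_keV,pe,compton,rayleigh,mu_en
1,38930.3,0.199157,2.82365,38930.3
1.1053,29182,0.199075,2.76149,29182
1.22168,21874.7,0.198985,2.69246,21874.7
1.35031,16397.2,0.198886,2.61674,16397.2
1.4925,12291.3,0.198776,2.53467,12291.3
1.64965,9199.58,0.198655,2.44682,9199.58
1.82335,6885.01,0.198522,2.35384,6885.01
2.01534,5152.27,0.198374,2.25651,5152.27
2.22754,3851.07,0.198212,2.15561,3851.07
2.46209,2878.49,0.198033,2.0519,2878.49
2.72134,2151.53,0.197835,1.94605,2151.53
3.00788,1608.11,0.197617,1.83867,1608.12
3.3246,1200.59,0.197377,1.73031,1200.59
3.67466,896.338,0.197113,1.62144,896.339
4.06159,669.114,0.196821,1.51257,669.116
4.48925,499.181,0.196501,1.40423,499.183
4.96195,372.406,0.196148,1.29702,372.408
5.48442,277.692,0.19576,1.19162,277.694
6.0619,207.046,0.195334,1.08881,207.048
6.70019,154.296,0.194865,0.989369,154.298
7.40568,114.985,0.194351,0.894095,114.988
8.18547,85.6784,0.193786,0.803692,85.6814
9.04736,63.8128,0.193167,0.718746,63.8161
10,47.5274,0.192489,0.639682,47.531
11.053,35.3746,0.191747,0.566746,35.3785
12.2168,26.3292,0.190935,0.500015,26.3336
13.5031,19.5968,0.190049,0.439412,19.6016
14.925,14.5859,0.189081,0.384737,14.5911
16.4965,10.8419,0.188027,0.335697,10.8476
18.2335,8.05842,0.18688,0.291939,8.06461
20.1534,5.98457,0.185633,0.253074,5.99131
22.2754,4.40002,0.184281,0.2187,4.40736
24.6209,3.23502,0.182817,0.188415,3.24299
27.2134,2.37847,0.181234,0.161832,2.38712
30.0788,1.74845,0.179527,0.138583,1.75781
33.246,1.27797,0.177689,0.118324,1.2881
36.7466,0.934094,0.175717,0.100735,0.945019
40.6159,0.682329,0.173604,0.0855212,0.694092
44.8925,0.496729,0.171349,0.0724114,0.509369
49.6195,0.361615,0.168947,0.0611572,0.375164
54.8442,0.262478,0.166397,0.0515317,0.276967
60.619,0.190394,0.163699,0.0433289,0.205848
67.0019,0.137604,0.160855,0.0363629,0.154041
74.0568,0.0994504,0.157866,0.0304668,0.116886
81.8547,0.0717977,0.154739,0.0254923,0.0902374
90.4736,0.0516444,0.151478,0.021308,0.0710873
100,0.0371481,0.148092,0.0177987,0.0575853
110.53,0.026493,0.144591,0.0148636,0.0479076
122.168,0.0188941,0.140986,0.0124155,0.0412608
135.031,0.0134748,0.137289,0.0103789,0.0367603
149.25,0.00960987,0.133514,0.00868917,0.0337733
164.965,0.00669841,0.129675,0.00729084,0.0316916
182.335,0.0046634,0.125787,0.00613683,0.0304317
201.534,0.00321721,0.121866,0.00518717,0.0297003
222.754,0.00198799,0.117925,0.0044081,0.0291207
246.209,0.00122843,0.113979,0.00377113,0.0289417
272.134,0.000759076,0.110042,0.00325231,0.0289805
300.788,0.000474718,0.106125,0.00283146,0.0291297
332.46,0.000463811,0.102239,0.0024916,0.0294762
367.466,0.000453154,0.0983952,0.00221843,0.0297456
406.159,0.000423055,0.0946003,0.00199991,0.0299179
448.925,0.000306806,0.0908616,0.00182593,0.0299263
496.195,0.000222501,0.0871849,0.00168805,0.0298892
548.442,0.000161361,0.0835748,0.00157922,0.0297986
606.19,0.000117022,0.080035,0.00149365,0.029649
670.019,8.4866e-05,0.0765684,0.00142659,0.0294373
740.568,6.15462e-05,0.0731774,0.00137419,0.0291619
818.547,4.46343e-05,0.0698641,0.00133337,0.0288225
904.736,3.23695e-05,0.0666301,0.00130165,0.02842
1000,2.34749e-05,0.0634772,0.00127708,0.0279561
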