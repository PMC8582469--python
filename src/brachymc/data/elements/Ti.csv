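# Element photon interaction data: Ti (Z=22)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Anchored element (totals transcribed, E>=10 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=22 A=47.867 k_edge_keV=4.966 k_yield=0.219 k_photo_fraction=0.88
# k_lines_keV=4.51 k_line_weights=1
E_keV,pe,compton,rayleigh,mu_en
1,8407.37,0.183411,3.64958,8407.37
1.1053,6348.57,0.183336,3.58002,6348.57
1.22168,4793.93,0.183253,3.50183,4793.93
1.35031,3619.98,0.183161,3.41495,3619.99
1.4925,2733.52,0.18306,3.31956,2733.52
1.64965,2064.13,0.182949,3.21611,2064.13
1.82335,1558.67,0.182826,3.10528,1558.67
2.01534,1176.98,0.18269,2.98791,1176.98
2.22754,888.76,0.182541,2.86497,888.76
2.46209,671.119,0.182376,2.73745,671.12
2.72134,506.775,0.182194,2.6063,506.776
3.00788,382.676,0.181993,2.47241,382.677
3.3246,288.966,0.181772,2.33653,288.967
3.67466,218.204,0.181528,2.19937,218.205
4.06159,164.77,0.18126,2.06154,164.771
4.48925,124.421,0.180965,1.92366,124.422
4.96195,93.9525,0.18064,1.7864,93.9542
4.96575,93.7507,0.180637,1.78536,93.7524
4.96625,781.037,0.180637,1.78522,644.345
5.48442,591.211,0.180283,1.65053,497.518
6.0619,446.435,0.17989,1.5169,382.426
6.70019,337.111,0.179459,1.38648,293.383
7.40568,254.559,0.178985,1.26028,224.686
8.18547,192.223,0.178465,1.13929,171.814
9.04736,145.151,0.177895,1.02442,131.21
10,109.606,0.17727,0.916422,100.083
11.053,82.7658,0.176587,0.869752,76.261
12.2168,62.4981,0.175839,0.781192,58.0556
13.5031,47.1935,0.175023,0.674028,44.1601
14.925,35.6367,0.174132,0.562685,33.5662
16.4965,26.6957,0.173161,0.514082,25.2944
18.2335,19.9895,0.172105,0.446823,19.0423
20.1534,14.9594,0.170957,0.377197,14.3204
22.2754,11.1175,0.169711,0.360132,10.6904
24.6209,8.26223,0.168363,0.317387,7.97789
27.2134,6.14029,0.166905,0.263179,5.95214
30.0788,4.5625,0.165333,0.207611,4.43929
33.246,3.36765,0.163641,0.193107,3.28893
36.7466,2.48572,0.161824,0.162977,2.43698
40.6159,1.83338,0.159879,0.131376,1.80498
44.8925,1.34666,0.157801,0.117519,1.33223
49.6195,0.989154,0.155589,0.093504,0.984305
54.8442,0.724647,0.153241,0.0829204,0.726506
60.619,0.53054,0.150757,0.0675908,0.537165
67.0019,0.387046,0.148137,0.0648226,0.397163
74.0568,0.282362,0.145385,0.0529746,0.295105
81.8547,0.205761,0.142505,0.0406963,0.220558
90.4736,0.149374,0.139502,0.036449,0.165845
100,0.10844,0.136384,0.0272761,0.126319
110.53,0.0782678,0.133159,0.0290224,0.0973738
122.168,0.0564907,0.129839,0.0261511,0.0766871
135.031,0.0407728,0.126434,0.0205582,0.0619548
149.25,0.0294282,0.122958,0.0135388,0.0515098
164.965,0.0209865,0.119422,0.0125656,0.0438931
182.335,0.0149569,0.115842,0.0105516,0.0386166
201.534,0.0106221,0.112231,0.00797673,0.0349656
222.754,0.00722879,0.108601,0.00774689,0.0321881
246.209,0.00491948,0.104968,0.00683962,0.0304243
272.134,0.0033479,0.101342,0.0055667,0.0293274
300.788,0.00229209,0.0977343,0.0041419,0.0286749
332.46,0.00196119,0.0941561,0.00314933,0.0286746
367.466,0.00167806,0.0906158,0.00230179,0.0286506
406.159,0.00140197,0.0871209,0.00164799,0.0285619
448.925,0.00102603,0.0836779,0.00138923,0.0283018
496.195,0.000750907,0.0802919,0.001157,0.0280708
548.442,0.000549555,0.0769672,0.00096594,0.0278427
606.19,0.000402194,0.0737072,0.000816338,0.0275987
670.019,0.000294347,0.0705147,0.000654667,0.0273257
740.568,0.000215419,0.0673918,0.000554388,0.0270148
818.547,0.000157655,0.0643404,0.000487671,0.0266601
904.736,0.000115381,0.0613622,0.000395802,0.0262585
1000,8.44418e-05,0.0584585,0.000367081,0.0258086
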