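# Element photon interaction data: Pb (Z=82)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Anchored element with K-edge duplicate points.
# Regenerate with tools/make_physics_tables.py.
# Z=82 A=207.2 k_edge_keV=88.005 k_yield=0.967 k_photo_fraction=0.79
# k_lines_keV=72.805,74.969,84.938 k_line_weights=0.29,0.5,0.21
E_keV,pe,compton,rayleigh,mu_en
1,25108.3,0.157929,12.3982,25108.3
1.1053,19944.2,0.157865,12.2791,19944.2
1.22168,15842.3,0.157793,12.1396,15842.3
1.35031,12584,0.157714,11.9776,12584
1.4925,9995.8,0.157628,11.791,9995.8
1.64965,7939.94,0.157532,11.5781,7939.94
1.82335,6306.92,0.157426,11.3377,6306.92
2.01534,5009.76,0.157309,11.0695,5009.77
2.22754,3979.4,0.15718,10.7736,3979.4
2.46209,3160.95,0.157038,10.4512,3160.95
2.72134,2510.83,0.156881,10.1042,2510.83
3.00788,1994.42,0.156708,9.73519,1994.42
3.3246,1584.23,0.156518,9.34705,1584.23
3.67466,1258.4,0.156308,8.943,1258.4
4.06159,999.58,0.156077,8.52617,999.581
4.48925,793.994,0.155823,8.09949,793.996
4.96195,630.692,0.155543,7.66556,630.694
5.48442,500.976,0.155236,7.22667,500.978
6.0619,397.94,0.154898,6.78489,397.942
6.70019,316.095,0.154526,6.3422,316.097
7.40568,251.083,0.154118,5.90065,251.085
8.18547,199.442,0.153671,5.46258,199.445
9.04736,158.423,0.15318,5.03062,158.425
10,125.84,0.152642,4.60775,125.842
11.053,121.288,0.152053,4.18747,121.291
12.2168,116.901,0.15141,3.79194,116.904
13.5031,112.673,0.150707,3.4199,112.676
14.925,108.597,0.14994,3.07017,108.601
16.4965,99.6519,0.149104,2.73012,99.6564
18.2335,91.2068,0.148194,2.42398,91.2117
20.1534,82.3705,0.147205,2.15576,82.3759
22.2754,63.2912,0.146133,1.95206,63.297
24.6209,48.6312,0.144972,1.72103,48.6375
27.2134,37.3669,0.143717,1.48607,37.3737
30.0788,28.7083,0.142363,1.26338,28.7157
33.246,21.9597,0.140906,1.11706,21.9677
36.7466,16.7975,0.139342,0.963751,16.8061
40.6159,12.8422,0.137667,0.821087,12.8516
44.8925,9.79049,0.135878,0.713132,9.80051
49.6195,7.46394,0.133973,0.604321,7.47469
54.8442,5.67961,0.131951,0.520982,5.6911
60.619,4.32052,0.129812,0.441542,4.33277
67.0019,3.28226,0.127556,0.384261,3.2953
74.0568,2.49351,0.125186,0.323951,2.50733
81.8547,1.89418,0.122706,0.26858,1.90881
88.0006,1.55246,0.120847,0.236877,1.56766
88.0094,7.32456,0.120844,0.236838,2.48019
90.4736,6.81336,0.120121,0.227049,2.43149
100,5.24143,0.117436,0.19013,2.19712
110.53,4.03417,0.114659,0.171706,1.91996
122.168,3.10497,0.1118,0.147258,1.63866
135.031,2.3898,0.108869,0.120615,1.37485
149.25,1.83935,0.105875,0.0941832,1.1389
164.965,1.41058,0.102831,0.0836983,0.931108
182.335,1.08155,0.0997479,0.069813,0.755626
201.534,0.829441,0.0966382,0.0555006,0.610126
222.754,0.637718,0.0935132,0.0533899,0.492068
246.209,0.490311,0.0903843,0.0464876,0.396006
272.134,0.376977,0.087262,0.0370968,0.31847
300.788,0.289895,0.0841559,0.0270272,0.256342
332.46,0.224519,0.0810749,0.0254857,0.208092
367.466,0.173885,0.0780264,0.0213847,0.169483
406.159,0.134807,0.0750171,0.0167556,0.138816
448.925,0.105098,0.0720524,0.0152783,0.114916
496.195,0.081936,0.0691368,0.012352,0.0958194
548.442,0.0641134,0.066274,0.0112752,0.0807895
606.19,0.0501849,0.0634669,0.00963712,0.0687694
670.019,0.0392962,0.0607179,0.00946192,0.0591478
740.568,0.0307701,0.0580289,0.00841177,0.0514203
818.547,0.0240427,0.0554015,0.00725358,0.0451482
904.736,0.018652,0.052837,0.00697933,0.0399593
1000,0.0144699,0.0503367,0.00621333,0.0357753
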