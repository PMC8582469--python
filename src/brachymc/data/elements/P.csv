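# Element photon interaction data: P (Z=15)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel log-log interpolated in Z between anchor elements (approximate below ~25 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=15 A=30.974 k_edge_keV=2.146 k_yield=0.0 k_photo_fraction=0.0
E_keV,pe,compton,rayleigh,mu_en
1,30944,0.193256,2.55711,30944
1.1053,23238.8,0.193177,2.49922,23238.8
1.22168,17452.3,0.193089,2.43509,17452.3
1.35031,13106.6,0.192993,2.36493,13106.6
1.4925,9843.03,0.192887,2.2891,9843.03
1.64965,7374.83,0.192769,2.20812,7374.83
1.82335,5524.86,0.192639,2.12263,5524.86
2.01534,4138.33,0.192497,2.03333,4138.33
2.22754,3094.12,0.192339,1.94093,3094.12
2.46209,2313.39,0.192165,1.84611,2313.39
2.72134,1729.66,0.191973,1.74947,1729.66
3.00788,1293.16,0.191762,1.65156,1293.16
3.3246,965.12,0.191529,1.55284,965.122
3.67466,720.296,0.191272,1.45377,720.297
4.06159,537.484,0.19099,1.35478,537.485
4.48925,400.683,0.190679,1.25639,400.684
4.96195,298.701,0.190336,1.15916,298.702
5.48442,222.507,0.18996,1.06372,222.509
6.0619,165.724,0.189546,0.970788,165.726
6.70019,123.337,0.189091,0.881083,123.339
7.40568,91.7907,0.188592,0.795311,91.7934
8.18547,68.2993,0.188044,0.714096,68.3022
9.04736,50.7849,0.187444,0.637942,50.7881
10,37.7618,0.186786,0.5672,37.7653
11.053,28.0493,0.186066,0.502061,28.0532
12.2168,20.835,0.185278,0.442562,20.8392
13.5031,15.4762,0.184418,0.388608,15.4808
14.925,11.4957,0.183479,0.339995,11.5007
16.4965,8.52519,0.182456,0.296444,8.53069
18.2335,6.32175,0.181343,0.257623,6.32775
20.1534,4.68416,0.180133,0.223175,4.6907
22.2754,3.43821,0.178821,0.192734,3.44532
24.6209,2.52367,0.1774,0.165936,2.5314
27.2134,1.85239,0.175864,0.142432,1.86078
30.0788,1.35947,0.174207,0.121892,1.36855
33.246,0.992265,0.172424,0.104008,1.00209
36.7466,0.724247,0.17051,0.0884931,0.734848
40.6159,0.528317,0.168461,0.0750843,0.539732
44.8925,0.384155,0.166272,0.0635392,0.39642
49.6195,0.27933,0.163941,0.0536361,0.292478
54.8442,0.202555,0.161467,0.0451728,0.216614
60.619,0.146792,0.158849,0.037966,0.161787
67.0019,0.106023,0.156089,0.0318502,0.121974
74.0568,0.0765772,0.153189,0.0266775,0.0934961
81.8547,0.0552577,0.150154,0.0223161,0.073151
90.4736,0.0397485,0.14699,0.0186499,0.0586153
100,0.0285922,0.143704,0.0155769,0.0484239
110.53,0.020406,0.140307,0.0130083,0.041186
122.168,0.0145635,0.136809,0.0108671,0.0362675
135.031,0.0103938,0.133221,0.00908685,0.0329894
149.25,0.00741794,0.129558,0.00761058,0.0308654
164.965,0.00518534,0.125833,0.00638963,0.029438
182.335,0.00362072,0.12206,0.00538261,0.0286255
201.534,0.00250743,0.118255,0.00455445,0.0282059
222.754,0.00157135,0.114431,0.00387552,0.0279002
246.209,0.000984736,0.110602,0.00332087,0.0278768
272.134,0.000617114,0.106781,0.00286948,0.0280024
300.788,0.000390967,0.10298,0.00250367,0.0281969
332.46,0.000371219,0.0992102,0.00220855,0.028524
367.466,0.000352468,0.0954798,0.00197158,0.028777
406.159,0.00032114,0.0917973,0.00178222,0.0289421
448.925,0.000232701,0.0881694,0.00163161,0.0289746
496.195,0.000168617,0.0846017,0.00151235,0.0289563
548.442,0.000122182,0.0810985,0.0014183,0.0288812
606.19,8.85338e-05,0.0776636,0.0013444,0.0287455
670.019,6.41524e-05,0.0742997,0.00128653,0.0285469
740.568,4.64854e-05,0.0710092,0.00124135,0.0282846
818.547,3.36838e-05,0.067794,0.00120616,0.0279589
904.736,2.44076e-05,0.0646559,0.00117884,0.0275709
1000,1.76859e-05,0.0615964,0.00115769,0.0271227
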