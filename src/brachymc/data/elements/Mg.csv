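# Element photon interaction data: Mg (Z=12)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel log-log interpolated in Z between anchor elements (approximate below ~25 keV).
# Regenerate with tools/make_physics_tables.py.
# Z=12 A=24.305 k_edge_keV=1.305 k_yield=0.0 k_photo_fraction=0.0
E_keV,pe,compton,rayleigh,mu_en
1,15826.2,0.197026,2.05101,15826.2
1.1053,11962.4,0.196946,2,11962.4
1.22168,9041.93,0.196857,1.94402,9041.93
1.35031,6834.44,0.196758,1.88333,6834.45
1.4925,5165.89,0.19665,1.81831,5165.89
1.64965,3884.45,0.19653,1.74947,3884.45
1.82335,2920.08,0.196398,1.67738,2920.08
2.01534,2194.39,0.196252,1.60262,2194.39
2.22754,1642.37,0.196091,1.52574,1642.38
2.46209,1229.22,0.195914,1.44726,1229.22
2.72134,920.002,0.195719,1.36763,920.003
3.00788,688.496,0.195503,1.28725,688.497
3.3246,513.239,0.195266,1.20648,513.24
3.67466,382.594,0.195004,1.12569,382.595
4.06159,285.095,0.194716,1.04528,285.096
4.48925,211.987,0.194399,0.965685,211.988
4.96195,157.626,0.19405,0.887416,157.628
5.48442,117.009,0.193666,0.811037,117.011
6.0619,86.8288,0.193244,0.73714,86.8311
6.70019,64.3224,0.192781,0.666307,64.3248
7.40568,47.6497,0.192272,0.599068,47.6524
8.18547,35.2826,0.191713,0.535863,35.2856
9.04736,26.0853,0.191101,0.47701,26.0885
10,19.2854,0.19043,0.4227,19.289
11.053,14.2255,0.189696,0.372994,14.2295
12.2168,10.4932,0.188893,0.327838,10.4975
13.5031,7.74011,0.188016,0.287089,7.74481
14.925,5.70935,0.187059,0.250532,5.71448
16.4965,4.20035,0.186016,0.217905,4.20596
18.2335,3.08976,0.184881,0.188921,3.09588
20.1534,2.27145,0.183647,0.163281,2.27811
22.2754,1.65771,0.18231,0.140689,1.66496
24.6209,1.2098,0.180861,0.120855,1.21768
27.2134,0.882913,0.179295,0.103506,0.891466
30.0788,0.644272,0.177606,0.0883853,0.653536
33.246,0.467973,0.175788,0.0752558,0.477988
36.7466,0.339916,0.173837,0.0638975,0.350724
40.6159,0.246787,0.171747,0.0541085,0.258424
44.8925,0.178712,0.169516,0.0457036,0.191217
49.6195,0.129416,0.167139,0.0385139,0.14282
54.8442,0.0935298,0.164617,0.032386,0.107864
60.619,0.0675651,0.161948,0.0271813,0.0828533
67.0019,0.0486925,0.159134,0.0227755,0.0649544
74.0568,0.0350915,0.156178,0.0190578,0.0523405
81.8547,0.0252795,0.153083,0.0159302,0.0435219
90.4736,0.0181864,0.149858,0.0133068,0.0374213
100,0.0130835,0.146508,0.0111125,0.0333021
110.53,0.00936089,0.143044,0.00928203,0.0305464
122.168,0.00669745,0.139478,0.0077591,0.0288249
135.031,0.00479184,0.13582,0.00649536,0.0278283
149.25,0.00342843,0.132085,0.00544947,0.0273333
164.965,0.00242032,0.128288,0.00458621,0.0271461
182.335,0.00170743,0.124442,0.00387574,0.0272001
201.534,0.00119813,0.120562,0.0032928,0.0273979
222.754,0.00078827,0.116663,0.00281612,0.0276308
246.209,0.000518618,0.11276,0.0024278,0.0279354
272.134,0.000341209,0.108865,0.00211274,0.0282607
300.788,0.00022607,0.10499,0.00185827,0.0285746
332.46,0.000194449,0.101146,0.00165369,0.0288965
367.466,0.000167251,0.0973426,0.00149,0.0291464
406.159,0.00014008,0.0935883,0.00135966,0.0293194
448.925,0.00010121,0.0898897,0.00125634,0.0294039
496.195,7.31256e-05,0.0862523,0.00117477,0.0294225
548.442,5.28343e-05,0.0826808,0.00111063,0.029373
606.19,3.81735e-05,0.0791788,0.00106035,0.0292543
670.019,2.75809e-05,0.0757493,0.00102107,0.0290661
740.568,1.99276e-05,0.0723946,0.000990457,0.028809
818.547,1.4398e-05,0.0691167,0.000966669,0.0284844
904.736,1.04028e-05,0.0659173,0.000948238,0.0280943
1000,7.51614e-06,0.0627981,0.000934003,0.0276414
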