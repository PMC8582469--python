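# Element photon interaction data: W (Z=74)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Photoelectric channel scaled from the lead anchor (Z-power law, own K edge; approximate).
# Regenerate with tools/make_physics_tables.py.
# Z=74 A=183.84 k_edge_keV=69.525 k_yield=0.957 k_photo_fraction=0.8
# k_lines_keV=57.982,59.318,67.244 k_line_weights=0.29,0.5,0.21
E_keV,pe,compton,rayleigh,mu_en
1,19687.1,0.160631,11.3446,19687.1
1.1053,15638,0.160566,11.2292,15638
1.22168,12421.7,0.160493,11.0943,12421.7
1.35031,9866.9,0.160413,10.9381,9866.9
1.4925,7837.56,0.160324,10.7587,7837.56
1.64965,6225.59,0.160227,10.5547,6225.59
1.82335,4945.17,0.160119,10.3254,4945.17
2.01534,3928.08,0.16,10.0704,3928.08
2.22754,3120.19,0.159869,9.79039,3120.19
2.46209,2478.45,0.159725,9.48653,2478.45
2.72134,1968.71,0.159565,9.16084,1968.71
3.00788,1563.8,0.159389,8.81578,1563.8
3.3246,1242.17,0.159196,8.45419,1242.17
3.67466,986.69,0.158983,8.079,986.691
4.06159,783.756,0.158748,7.69302,783.757
4.48925,622.559,0.158489,7.29885,622.561
4.96195,494.517,0.158205,6.89878,494.518
5.48442,392.808,0.157892,6.49482,392.81
6.0619,312.019,0.157548,6.08883,312.021
6.70019,247.845,0.15717,5.68263,247.847
7.40568,196.871,0.156755,5.27818,196.873
8.18547,156.38,0.1563,4.87771,156.382
9.04736,124.217,0.155801,4.48375,124.22
10,98.669,0.155254,4.09913,98.6719
11.053,95.1001,0.154655,3.72682,95.1033
12.2168,91.6603,0.154,3.36975,91.6638
13.5031,88.3449,0.153285,3.03061,88.3487
14.925,85.1494,0.152505,2.71163,85.1536
16.4965,78.1356,0.151655,2.41447,78.1402
18.2335,71.514,0.150729,2.1401,71.5189
20.1534,64.5856,0.149724,1.88888,64.591
22.2754,49.6257,0.148633,1.66057,49.6317
24.6209,38.131,0.147452,1.45447,38.1375
27.2134,29.2988,0.146175,1.2695,29.3058
30.0788,22.5097,0.144798,1.10438,22.5173
33.246,17.2182,0.143317,0.957658,17.2264
36.7466,13.1707,0.141726,0.827834,13.1795
40.6159,10.0694,0.140022,0.713414,10.0789
44.8925,7.67658,0.138202,0.612943,7.68678
49.6195,5.85237,0.136265,0.525043,5.8633
54.8442,4.4533,0.134209,0.448419,4.46499
60.619,3.38766,0.132033,0.381869,3.40012
67.0019,2.57357,0.129739,0.324285,2.58683
69.5215,2.32553,0.128863,0.305107,2.33909
69.5285,11.0709,0.128861,0.305057,3.69762
74.0568,9.31011,0.127328,0.274645,3.49203
81.8547,7.07239,0.124806,0.232016,3.07895
90.4736,5.34226,0.122176,0.195542,2.61862
100,4.10973,0.119445,0.164449,2.21965
110.53,3.16313,0.116621,0.138035,1.85277
122.168,2.43456,0.113713,0.115671,1.52811
135.031,1.8738,0.110731,0.0967961,1.24882
149.25,1.44221,0.107686,0.0809151,1.01341
164.965,1.10601,0.10459,0.067592,0.815137
182.335,0.848025,0.101455,0.056446,0.653045
201.534,0.650353,0.0982916,0.0471468,0.522007
222.754,0.500026,0.0951131,0.0394089,0.417773
246.209,0.384446,0.0919307,0.032987,0.33436
272.134,0.295582,0.088755,0.0276713,0.267956
300.788,0.227303,0.0855958,0.0232831,0.215357
332.46,0.176042,0.082462,0.0196709,0.174877
367.466,0.136341,0.0793614,0.0167066,0.142754
406.159,0.1057,0.0763006,0.0142822,0.117416
448.925,0.0824056,0.0732851,0.0123067,0.0977797
496.195,0.0642448,0.0703197,0.0107035,0.0821662
548.442,0.0502704,0.0674079,0.00940831,0.0699223
606.19,0.0393492,0.0645528,0.00836675,0.0601571
670.019,0.0308116,0.0617568,0.00753318,0.0523527
740.568,0.0241264,0.0590218,0.00686922,0.0460862
818.547,0.0188515,0.0563494,0.00634276,0.0409941
904.736,0.0146247,0.053741,0.00592708,0.0367711
1000,0.0113457,0.051198,0.00560011,0.0333486
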