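# Element photon interaction data: N (Z=7)
# Provenance: assembled from the published Hubbell-Seltzer/XCOM
#   compilations (transcribed anchors) with partial channels
#   reconstructed as documented in docs/methods.md.
#   Derived from the dry-air mixture identity.
# Regenerate with tools/make_physics_tables.py.
# Z=7 A=14.007 k_edge_keV=0.41 k_yield=0.0 k_photo_fraction=0.0
E_keV,pe,compton,rayleigh,mu_en
1,2500.99,0.19943,4.54004,2500.99
1.1053,1907.59,0.199349,3.96582,1907.59
1.22168,1454.98,0.199259,3.39744,1454.98
1.35031,1109.77,0.199159,2.86444,1109.77
1.4925,846.457,0.199049,2.38202,846.457
1.64965,638.058,0.198928,1.96373,638.058
1.82335,480.668,0.198794,1.59528,480.669
2.01534,361.802,0.198647,1.30073,361.802
2.22754,269.612,0.198484,1.25404,269.613
2.46209,200.913,0.198305,1.13421,200.915
2.72134,149.72,0.198107,0.981474,149.721
3.00788,111.751,0.197889,0.838898,111.752
3.3246,88.5714,0.197648,1.24781,88.5728
3.67466,70.2001,0.197383,1.44607,70.2016
4.06159,55.085,0.197092,1.44416,55.0866
4.48925,40.8871,0.196771,1.11169,40.889
4.96195,30.3487,0.196418,0.841908,30.3505
5.48442,22.4296,0.196029,0.670022,22.4318
6.0619,16.5632,0.195602,0.52629,16.5655
6.70019,12.18,0.195133,0.436682,12.183
7.40568,8.95683,0.194618,0.34483,8.95987
8.18547,6.57799,0.194053,0.270591,6.58114
9.04736,4.80978,0.193433,0.229513,4.8134
10,3.51687,0.192754,0.17832,3.52049
11.053,2.55512,0.19201,0.185723,2.56051
12.2168,1.85638,0.191198,0.16481,1.86231
13.5031,1.34872,0.19031,0.129875,1.35449
14.925,0.979892,0.189341,0.0897012,0.985144
16.4965,0.70759,0.188285,0.0897652,0.714292
18.2335,0.510794,0.187137,0.075259,0.517822
20.1534,0.368691,0.185888,0.0551891,0.375737
22.2754,0.265774,0.184534,0.0625864,0.275679
24.6209,0.191586,0.183068,0.0567579,0.202266
27.2134,0.138107,0.181483,0.0432842,0.148403
30.0788,0.0995496,0.179773,0.0264707,0.108998
33.246,0.0716028,0.177933,0.0266368,0.0832501
36.7466,0.0515016,0.175958,0.0219619,0.0635843
40.6159,0.0370389,0.173843,0.0156586,0.0490706
44.8925,0.0266195,0.171584,0.0141246,0.0401152
49.6195,0.0191312,0.169179,0.0106976,0.0327942
54.8442,0.0137456,0.166626,0.00923193,0.0286996
60.619,0.00987717,0.163924,0.00728808,0.0254615
67.0019,0.00710607,0.161076,0.00647278,0.0242329
74.0568,0.00511242,0.158083,0.00525275,0.0230636
81.8547,0.00367731,0.154951,0.00403344,0.0222181
90.4736,0.00264317,0.151686,0.00339493,0.0222943
100,0.00189984,0.148296,0.00274071,0.0223708
110.53,0.00136594,0.14479,0.00223333,0.022939
122.168,0.000982076,0.14118,0.00181548,0.0235216
135.031,0.000706088,0.137478,0.00151276,0.024119
149.25,0.00050766,0.133697,0.00133797,0.0247316
164.965,0.000364995,0.129853,0.00099409,0.0253779
182.335,0.000262422,0.12596,0.000782066,0.0260421
201.534,0.000188675,0.122033,0.000683155,0.0267087
222.754,0.000135652,0.118087,0.000400227,0.027207
246.209,9.75306e-05,0.114136,0.000256586,0.0277146
272.134,7.01221e-05,0.110193,0.0002379,0.0282317
300.788,5.0416e-05,0.106271,0.000321561,0.0287514
332.46,3.62478e-05,0.10238,0.000203291,0.0290168
367.466,2.60613e-05,0.0985304,0.000191652,0.0292846
406.159,1.87374e-05,0.0947303,0.000233989,0.0295254
448.925,1.34717e-05,0.0909865,0.000149254,0.0296033
496.195,9.68583e-06,0.0873048,0.000155737,0.0296814
548.442,6.96387e-06,0.0836897,0.00010308,0.0296235
606.19,5.00685e-06,0.080145,0.000104561,0.0295359
670.019,3.5998e-06,0.0766736,3.40017e-05,0.0292868
740.568,2.58816e-06,0.073278,4.37474e-05,0.0290399
818.547,1.86082e-06,0.0699601,8.03936e-05,0.0287538
904.736,1.33789e-06,0.0667217,4.09427e-05,0.0283336
1000,9.61906e-07,0.0635644,7.36961e-05,0.0279196
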