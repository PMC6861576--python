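# Published vibrational assignments for BZL: scaled B3LYP/cc-pVDZ wavenumbers (cm-1),
# IR intensity (KM/mole), Raman activity (A^4/amu), observed IR and Raman bands (cm-1).
calc,ir_int,raman_act,obs_ir,obs_raman,assignment
3108,2.49,5.20,3106,,nu(CH)
3088,15.35,26.98,3088,,nu(CH)
3075,3.47,365.80,,3075,nu(CH)
3065,24.42,26.89,3062,,nu(CH)
3064,1.08,243.22,3062,3055,nu(CH)
3053,0.35,19.28,3045,3048,nu(CH)
1671,68.81,203.76,1685,1675,nu(C=O)
1669,276.24,19.99,1666,,nu(C=O)
1584,12.46,31.63,1582,,nu(Ring)
1457,0.67,16.09,1455,1456,nu(Ring)
1418,37.19,0.18,1405,,nu(Ring)
1314,1.79,5.38,1320,1320,nu(Ring)
1286,9.23,18.54,1288,1288,delta(CH)
1268,9.42,8.95,1266,,delta(CH)
1179,237.69,15.57,1185,1177,nu(CC)
1061,9.53,0.02,1061,1057,delta(CH)
1026,0.48,10.94,,1025,delta(CH)
1009,7.46,2.84,1012,,nu(Ring)
1003,0.21,90.43,1000,1000,nu(Ring)
966,0.30,0.67,965,,gamma(CH)
930,0.37,0.83,935,,gamma(CH)
848,75.99,0.23,,847,gamma(CH)
800,74.03,0.58,795,800,gamma(CH)
711,16.97,0.66,710,,tau(Ring)
699,25.71,15.00,700,700,delta(Ring)
679,50.13,1.75,678,,tau(Ring)
629,103.86,1.21,635,636,delta(Ring)
603,1.39,1.40,605,606,delta(Ring)
486,6.61,3.94,485,484,tau(Ring)
425,0.28,0.76,,425,tau(Ring)
401,0.02,2.39,,400,tau(Ring)
334,3.04,0.40,,336,tau(Ring)
277,32.96,0.02,,275,delta(Ring)
146,1.66,1.40,,148,tau(Ring)
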