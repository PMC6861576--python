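# Published vibrational assignments for DFB: scaled B3LYP/cc-pVDZ wavenumbers (cm-1),
# IR intensity (KM/mole), Raman activity (A^4/amu), observed IR and Raman bands (cm-1).
calc,ir_int,raman_act,obs_ir,obs_raman,assignment
3116,2.65,7.17,,3110,nu(CH)
3095,0.18,278.20,3100,3095,nu(CH)
3082,0.05,14.85,3083,,nu(CH)
1668,54.80,238.06,1670,1672,nu(C=O)
1666,267.94,28.23,1655,1658,nu(C=O)
1568,58.71,2.51,1555,,nu(Ring)
1387,28.78,0.18,1382,,nu(Ring)
1315,3.94,5.86,1320,1320,nu(Ring)
1312,10.57,0.91,1305,1306,nu(Ring)
1253,0.01,8.39,,1250,delta(CH)
1227,274.81,3.76,1235,,nu(CF)
1225,15.00,27.33,1215,1218,nu(CF)
1177,285.78,15.20,1160,1165,delta(CH)
1119,223.62,2.30,1110,,delta(CH)
1069,0.31,4.63,,1060,delta(CH)
1019,0.29,8.52,1020,,nu(CC)
970,0.01,0.42,,972,gamma(CH)
945,4.12,0.56,957,,gamma(CH)
841,99.96,1.68,845,850,gamma(CH)
840,64.44,2.64,,840,gamma(CH)
810,1.63,56.71,,808,nu(Ring)
806,4.83,7.99,805,,nu(Ring)
758,36.09,0.71,757,760,tau(Ring)
691,5.56,0.38,,700,tau(Ring)
619,4.80,2.26,,622,delta(Ring)
603,1.02,0.86,600,600,delta(Ring)
501,1.49,0.09,500,500,tau(Ring)
433,1.40,3.81,,435,tau(Ring)
415,19.67,0.28,,420,delta(Ring)
407,0.09,0.30,,405,tau(Ring)
356,1.07,2.29,,355,tau(C=O)
267,0.33,0.86,,270,tau(C=O)
261,26.65,0.65,,258,tau(Ring)
226,0.04,1.25,,225,tau(Ring)
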