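# Published vibrational assignments for DMB: scaled B3LYP/cc-pVDZ wavenumbers (cm-1),
# IR intensity (KM/mole), Raman activity (A^4/amu), observed IR and Raman bands (cm-1).
calc,ir_int,raman_act,obs_ir,obs_raman,assignment
3107,0.85,13.43,3100,,nu(CH)
3085,0.01,149.69,3070,3070,nu(CH)
3053,27.49,39.15,3050,3050,nu(CH)
3046,31.23,1.27,3045,3030,nu(CH)
3000,11.51,81.37,,3000,nu(CH3)
2998,15.50,71.18,,2995,nu(CH3)
2968,20.05,77.64,2965,2960,nu(CH3)
2967,4.41,195.52,2965,2960,nu(CH3)
2912,4.86,684.39,2910,2913,nu(CH3)
2911,44.50,38.39,2910,2913,nu(CH3)
1667,69.31,2.45,1720,,nu(C=O)
1665,290.83,24.15,1660,1660,nu(C=O)
1593,227.58,93.33,1598,,nu(Ring)
1592,32.38,713.12,,1580,nu(Ring)
1549,2.40,3.84,1555,,nu(Ring)
1411,40.78,2.71,,1410,delta(CH3)
1398,7.00,18.39,1400,,delta(CH3)
1379,10.23,0.08,1377,1377,delta(CH3)
1340,0.01,83.01,1345,1340,delta(CH3)
1339,0.23,11.38,1345,1340,delta(CH3)
1304,4.91,0.02,1302,1300,nu(Ring)
1188,0.42,52.18,,1190,delta(CH)
1186,250.05,18.64,1184,1180,delta(CH)
1143,245.11,10.23,1145,,delta(CH)
1089,18.74,1.26,1085,,delta(CH)
1024,0.13,9.29,1025,,nu(CC)
1009,4.09,0.70,,1010,delta(CH3)
992,10.35,0.06,998,,delta(CH3)
957,0.65,7.13,955,,delta(CH3)
862,55.22,0.87,870,870,gamma(CH)
833,5.11,3.05,835,836,gamma(CH)
824,48.77,0.83,825,,gamma(CH)
812,18.90,2.71,808,810,nu(Ring)
787,0.09,61.46,,788,nu(Ring)
768,6.66,2.82,770,,gamma(CH)
738,97.08,1.30,740,,gamma(CH)
624,0.79,2.16,,625,delta(Ring)
605,3.68,1.14,607,603,delta(Ring)
587,54.99,0.33,588,,delta(Ring)
495,15.53,3.35,494,,tau(Ring)
414,0.28,6.25,,412,tau(Ring)
401,6.72,1.73,,400,delta(Ring)
355,0.30,0.33,,357,tau(Ring)
341,0.15,2.26,,340,tau(CH3)
249,12.12,1.04,,250,tau(Ring)
248,19.01,1.50,,244,tau(C=O)
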