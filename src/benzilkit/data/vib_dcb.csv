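# Published vibrational assignments for DCB: scaled B3LYP/cc-pVDZ wavenumbers (cm-1),
# IR intensity (KM/mole), Raman activity (A^4/amu), observed IR bands (cm-1).
# No Raman bands were tabulated for this molecule.
calc,ir_int,raman_act,obs_ir,obs_raman,assignment
3095,0.02,2.37,3100,,nu(CH)
3082,0.01,71.32,3080,,nu(CH)
3082,0.18,6.34,3080,,nu(CH)
1670,61.75,4.31,1665,,nu(C=O)
1667,304.59,2.95,1665,,nu(C=O)
1573,36.71,7.37,1575,,nu(Ring)
1547,52.98,3.63,1535,,nu(Ring)
1302,5.74,2.02,1308,,nu(Ring)
1298,14.46,0.43,1297,,nu(Ring)
1179,316.87,21.10,1177,,delta(CH)
1021,0.50,14.10,1015,,nu(CC)
971,0.17,0.52,965,,gamma(CH)
948,0.07,1.06,946,,gamma(CH)
862,54.58,0.12,858,,gamma(CH)
832,34.15,3.88,835,,nu(Ring)
769,46.83,0.28,766,,nu(Ring)
733,0.45,35.82,735,,gamma(CH)
719,16.68,1.11,710,,nu(CCl)
688,0.82,0.89,690,,nu(CCl)
476,3.13,0.92,470,,tau(Ring)
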