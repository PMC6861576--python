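# Published vibrational assignments for DBB: scaled B3LYP/cc-pVDZ wavenumbers (cm-1),
# IR intensity (KM/mole), Raman activity (A^4/amu), observed IR bands (cm-1).
# No Raman bands were tabulated for this molecule.
calc,ir_int,raman_act,obs_ir,obs_raman,assignment
3114,1.74,4.77,3100,,nu(CH)
3088,1.16,2.27,3090,,nu(CH)
3082,0.47,8.58,3050,,nu(CH)
1669,64.43,5.82,1670,,nu(C=O)
1666,318.06,3.70,1650,,nu(C=O)
1568,336.69,9.76,1570,,nu(Ring)
1273,14.10,2.13,1275,,nu(Ring)
1179,295.30,2.61,1177,,delta(CH)
1081,12.85,1.04,1080,,delta(CH)
1020,0.75,20.91,1015,,nu(CC)
970,0.20,0.53,965,,gamma(CH)
947,0.04,1.34,945,,gamma(CH)
829,26.95,4.49,833,,nu(Ring)
764,50.50,0.24,763,,nu(Ring)
724,7.13,2.01,725,,gamma(CH)
664,14.08,6.31,670,,nu(CBr)
611,4.21,1.11,610,,nu(CBr)
496,28.90,1.28,498,,delta(Ring)
467,4.82,0.70,465,,tau(Ring)
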