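# Published top-10 PatchDock conformations per receptor-ligand complex for the benzil
# series docked against 3WMT (feruloyl esterase), 2H4Z (bisphosphoglycerate mutase)
# and 2EEP (prolyl aminopeptidase). Score units are the server's own (opaque).
receptor,ligand,rank,global_energy,attractive_vdw,repulsive_vdw,ace
3WMT,BZL,1,-23.12,-9.89,4.69,-8.89
3WMT,BZL,2,-22.40,-9.37,3.32,-7.28
3WMT,BZL,3,-22.39,-9.33,1.97,-6.41
3WMT,BZL,4,-21.62,-9.92,3.44,-6.90
3WMT,BZL,5,-21.33,-8.85,3.53,-7.27
3WMT,BZL,6,-21.21,-9.44,2.25,-6.61
3WMT,BZL,7,-20.80,-9.32,1.99,-7.46
3WMT,BZL,8,-19.79,-10.17,3.96,-6.08
3WMT,BZL,9,-18.92,-8.30,4.00,-6.42
3WMT,BZL,10,-18.73,-13.07,6.32,-3.36
3WMT,DMB,1,-24.78,-10.07,1.31,-7.12
3WMT,DMB,2,-24.54,-10.40,5.70,-9.13
3WMT,DMB,3,-24.37,-11.14,3.77,-7.44
3WMT,DMB,4,-24.10,-10.37,1.78,-6.51
3WMT,DMB,5,-24.03,-12.91,5.20,-8.43
3WMT,DMB,6,-23.32,-11.90,5.83,-7.53
3WMT,DMB,7,-23.20,-9.63,1.00,-6.50
3WMT,DMB,8,-22.87,-9.18,1.90,-7.11
3WMT,DMB,9,-22.65,-11.20,2.45,-5.43
3WMT,DMB,10,-22.40,-13.66,14.98,-9.73
3WMT,DFB,1,-25.78,-13.65,5.34,-6.05
3WMT,DFB,2,-23.18,-10.64,1.29,-5.33
3WMT,DFB,3,-22.44,-10.90,1.30,-4.80
3WMT,DFB,4,-21.90,-12.53,2.69,-3.31
3WMT,DFB,5,-19.70,-12.95,4.31,-5.21
3WMT,DFB,6,-19.40,-11.26,3.22,-4.23
3WMT,DFB,7,-19.19,-9.89,2.94,-5.38
3WMT,DFB,8,-18.18,-9.30,3.84,-5.60
3WMT,DFB,9,-17.20,-11.55,5.01,-3.63
3WMT,DFB,10,-17.08,-9.03,4.74,-4.81
3WMT,DCB,1,-25.24,-11.33,3.80,-8.31
3WMT,DCB,2,-23.64,-13.42,5.13,-7.17
3WMT,DCB,3,-23.61,-11.87,2.71,-6.66
3WMT,DCB,4,-23.00,-10.29,3.92,-6.87
3WMT,DCB,5,-22.06,-10.67,4.99,-7.58
3WMT,DCB,6,-21.63,-10.08,2.45,-5.91
3WMT,DCB,7,-21.53,-13.29,10.29,-6.19
3WMT,DCB,8,-21.04,-10.61,0.89,-5.94
3WMT,DCB,9,-19.80,-9.87,4.32,-6.61
3WMT,DCB,10,-19.47,-9.76,2.88,-4.81
3WMT,DBB,1,-26.46,-11.30,1.12,-6.81
3WMT,DBB,2,-25.22,-10.66,1.28,-6.91
3WMT,DBB,3,-21.31,-9.77,4.16,-6.80
3WMT,DBB,4,-20.62,-13.87,2.51,-3.93
3WMT,DBB,5,-20.27,-9.74,1.11,-5.84
3WMT,DBB,6,-19.88,-8.86,2.12,-5.46
3WMT,DBB,7,-19.85,-13.10,14.49,-8.47
3WMT,DBB,8,-19.53,-8.49,3.25,-6.23
3WMT,DBB,9,-19.39,-9.99,3.26,-5.56
3WMT,DBB,10,-19.26,-10.86,2.66,-4.50
2H4Z,BZL,1,-27.52,-12.80,3.27,-8.97
2H4Z,BZL,2,-22.05,-9.77,3.30,-6.83
2H4Z,BZL,3,-20.75,-13.94,2.85,-2.92
2H4Z,BZL,4,-20.26,-10.66,5.96,-8.11
2H4Z,BZL,5,-19.95,-9.22,2.02,-5.30
2H4Z,BZL,6,-19.25,-11.99,0.61,-5.16
2H4Z,BZL,7,-18.23,-8.30,0.93,-5.54
2H4Z,BZL,8,-17.52,-10.49,2.56,-2.70
2H4Z,BZL,9,-17.39,-9.36,2.64,-5.59
2H4Z,BZL,10,-15.93,-8.29,4.67,-5.19
2H4Z,DMB,1,-32.38,-16.91,9.27,-11.11
2H4Z,DMB,2,-27.40,-13.48,3.67,-8.78
2H4Z,DMB,3,-27.20,-13.09,3.24,-8.75
2H4Z,DMB,4,-21.92,-11.62,4.16,-5.09
2H4Z,DMB,5,-21.64,-14.85,2.80,-2.93
2H4Z,DMB,6,-21.55,-9.89,4.28,-6.83
2H4Z,DMB,7,-19.46,-9.76,4.49,-6.84
2H4Z,DMB,8,-19.21,-9.37,2.83,-6.02
2H4Z,DMB,9,-18.82,-10.18,5.51,-6.19
2H4Z,DMB,10,-18.80,-9.17,1.63,-4.77
2H4Z,DFB,1,-21.76,-12.66,2.37,-5.57
2H4Z,DFB,2,-18.13,-13.01,3.33,-3.39
2H4Z,DFB,3,-15.95,-8.81,2.97,-4.31
2H4Z,DFB,4,-15.59,-10.01,4.89,-4.62
2H4Z,DFB,5,-15.16,-7.62,2.25,-5.32
2H4Z,DFB,6,-14.79,-10.57,3.89,-1.96
2H4Z,DFB,7,-14.44,-8.81,1.99,-2.30
2H4Z,DFB,8,-14.39,-9.84,4.14,-4.78
2H4Z,DFB,9,-13.51,-11.55,7.07,-1.73
2H4Z,DFB,10,-13.41,-11.71,2.13,0.59
2H4Z,DCB,1,-25.92,-14.18,8.44,-9.43
2H4Z,DCB,2,-21.53,-8.95,3.33,-7.15
2H4Z,DCB,3,-20.65,-10.61,1.11,-4.54
2H4Z,DCB,4,-20.48,-9.81,2.22,-7.83
2H4Z,DCB,5,-20.16,-11.06,3.39,-4.24
2H4Z,DCB,6,-19.54,-14.09,3.86,-2.97
2H4Z,DCB,7,-19.26,-12.46,10.09,-7.56
2H4Z,DCB,8,-19.10,-11.61,3.24,-5.57
2H4Z,DCB,9,-18.76,-11.80,2.55,-5.18
2H4Z,DCB,10,-17.44,-13.62,10.31,-4.34
2H4Z,DBB,1,-23.46,-10.31,2.62,-6.75
2H4Z,DBB,2,-22.33,-10.82,0.81,-7.18
2H4Z,DBB,3,-20.85,-11.57,8.33,-7.69
2H4Z,DBB,4,-18.65,-10.71,3.33,-5.59
2H4Z,DBB,5,-18.52,-10.01,4.13,-5.81
2H4Z,DBB,6,-18.39,-10.40,4.65,-4.52
2H4Z,DBB,7,-17.95,-11.40,0.15,-1.30
2H4Z,DBB,8,-17.32,-9.96,1.01,-2.43
2H4Z,DBB,9,-17.24,-10.11,0.98,-4.89
2H4Z,DBB,10,-16.36,-6.71,2.06,-6.01
2EEP,BZL,1,-36.74,-16.59,4.58,-11.17
2EEP,BZL,2,-34.42,-14.40,2.68,-11.17
2EEP,BZL,3,-31.79,-15.81,5.21,-8.95
2EEP,BZL,4,-30.99,-13.96,3.70,-8.34
2EEP,BZL,5,-30.85,-15.06,2.24,-7.08
2EEP,BZL,6,-30.56,-14.39,3.85,-9.56
2EEP,BZL,7,-30.24,-13.02,1.57,-8.33
2EEP,BZL,8,-30.06,-12.17,0.41,-8.34
2EEP,BZL,9,-29.29,-14.15,4.94,-9.42
2EEP,BZL,10,-29.20,-11.20,2.50,-9.54
2EEP,DMB,1,-33.30,-13.90,4.36,-10.59
2EEP,DMB,2,-33.04,-14.99,3.22,-8.87
2EEP,DMB,3,-31.69,-15.96,2.91,-8.50
2EEP,DMB,4,-27.98,-16.70,17.54,-12.21
2EEP,DMB,5,-27.86,-14.64,4.39,-7.72
2EEP,DMB,6,-27.66,-14.57,4.62,-7.76
2EEP,DMB,7,-27.41,-15.08,4.11,-6.69
2EEP,DMB,8,-27.26,-15.93,2.53,-6.04
2EEP,DMB,9,-26.86,-12.38,0.89,-8.36
2EEP,DMB,10,-26.21,-11.82,2.20,-8.26
2EEP,DFB,1,-31.74,-17.64,5.76,-6.61
2EEP,DFB,2,-31.10,-17.47,7.28,-6.83
2EEP,DFB,3,-31.09,-16.84,4.23,-6.74
2EEP,DFB,4,-30.95,-14.87,4.37,-9.02
2EEP,DFB,5,-29.59,-17.34,8.59,-6.64
2EEP,DFB,6,-28.02,-15.47,5.12,-7.50
2EEP,DFB,7,-27.33,-12.04,1.70,-7.48
2EEP,DFB,8,-26.95,-12.05,2.34,-7.43
2EEP,DFB,9,-26.87,-12.56,5.46,-9.25
2EEP,DFB,10,-26.80,-14.20,1.98,-4.98
2EEP,DCB,1,-36.83,-18.77,9.02,-10.91
2EEP,DCB,2,-35.64,-16.44,3.86,-9.55
2EEP,DCB,3,-35.31,-17.56,7.77,-9.57
2EEP,DCB,4,-33.82,-15.25,3.39,-8.73
2EEP,DCB,5,-32.32,-13.85,4.93,-10.42
2EEP,DCB,6,-32.25,-13.36,1.05,-10.30
2EEP,DCB,7,-31.96,-13.10,4.56,-10.43
2EEP,DCB,8,-30.45,-15.06,3.75,-8.84
2EEP,DCB,9,-27.90,-12.16,5.71,-10.31
2EEP,DCB,10,-27.69,-15.23,4.91,-7.24
2EEP,DBB,1,-32.51,-14.53,3.12,-8.32
2EEP,DBB,2,-31.97,-14.38,2.22,-8.40
2EEP,DBB,3,-31.83,-15.09,1.41,-7.99
2EEP,DBB,4,-30.15,-15.36,6.11,-9.60
2EEP,DBB,5,-28.43,-14.71,4.88,-7.93
2EEP,DBB,6,-27.52,-13.74,2.83,-7.21
2EEP,DBB,7,-26.42,-13.18,1.81,-7.16
2EEP,DBB,8,-26.34,-12.74,1.54,-7.00
2EEP,DBB,9,-25.86,-18.82,19.12,-8.12
2EEP,DBB,10,-25.60,-15.40,3.15,-5.53
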