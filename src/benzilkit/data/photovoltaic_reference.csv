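# Published photovoltaic-modelling table for the benzil dye series (DSSC sensitizer screening).
# Columns: oscillator strength f, light-harvesting efficiency, absorption maximum,
# vertical excitation energy E(0,0), frontier orbital energies, orbital gap,
# ground/excited-state oxidation energies, TiO2 conduction-band energy, injection free energy.
id,f,lhe,lambda_max_nm,e00,e_homo,e_lumo,gap,e_dye,e_dye_star,e_cb,dg_inject
BZL,0.608,0.753396,276.39,4.486414,-6.59604,-2.62862,3.967422,6.596043,2.109629,-4.00,-1.89037
DMB,0.8355,0.853951,286.99,4.320708,-6.42352,-2.46399,3.959531,6.423523,2.102815,-4.00,-1.89718
DFB,0.7299,0.813748,271.83,4.561675,-6.79496,-2.7293,4.065655,6.794959,2.233284,-4.00,-1.76672
DCB,0.9581,0.889871,277.26,4.472336,-6.82217,-1.75405,5.068123,6.82217,2.349834,-4.00,-1.65017
DBB,1.036,0.9079,279.96,4.429204,-6.84639,-2.84359,4.002797,6.846388,2.417184,-4.00,-1.58282
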