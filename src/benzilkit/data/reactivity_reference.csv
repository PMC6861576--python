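# Published conceptual-DFT global reactivity descriptors for the benzil series.
# IP/EA are vertical values in eV; chi/mu/eta/omega in eV, s in 1/eV.
id,ip,ea,chi,mu,eta,s,omega
BZL,8.748,6.065,7.407,-7.407,1.342,0.745,20.441
DMB,8.689,5.880,7.285,-7.285,1.405,0.712,18.887
DFB,8.681,5.702,7.192,-7.192,1.490,0.671,17.357
DCB,8.174,5.708,6.941,-6.941,1.233,0.811,19.537
DBB,8.694,5.905,7.300,-7.300,1.395,0.716,19.100
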