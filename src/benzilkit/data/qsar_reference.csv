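# Published QSAR design table for the benzil series: reactivity descriptors plus
# docking binding energies (rank-1 atomic contact energy, score units) per receptor.
id,ip,ea,chi,mu,eta,s,omega,be_3WMT,be_2H4Z,be_2EEP
BZL,8.748,6.065,7.407,-7.407,1.342,0.745,20.441,-8.89,-8.97,-11.17
DMB,8.689,5.880,7.285,-7.285,1.405,0.712,18.887,-7.12,-11.11,-10.59
DFB,8.681,5.702,7.192,-7.192,1.490,0.671,17.357,-6.05,-5.57,-6.61
DCB,8.174,5.708,6.941,-6.941,1.233,0.811,19.537,-8.31,-9.43,-10.91
DBB,8.694,5.905,7.300,-7.300,1.395,0.716,19.100,-6.81,-6.75,-8.32
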