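# Published NLO scalar properties for the benzil series.
# mu in Debye; alpha in 1e-23 esu; beta (first hyperpolarizability) in 1e-30 esu;
# gamma (second hyperpolarizability) in 1e-37 esu.
id,mu_debye,alpha_1e23_esu,beta_1e30_esu,gamma_1e37_esu
BZL,2.4212,2.275,1.927,-3.807
DMB,2.7404,2.757,3.989,-14.386
DFB,1.4873,2.305,3.716,-13.540
DCB,1.3013,2.745,6.704,-20.195
DBB,1.3607,2.966,8.295,-25.090
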