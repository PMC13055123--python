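salt,mg_per_l,mw_g_per_mol,cation,cations_per_formula,cation_charge
NaCl,6995.5,58.44,Na,1,1
NaHCO3,2438.0,84.01,Na,1,1
Na2HPO4,71.02,141.96,Na,2,1
NaH2PO4.H2O,62.5,137.99,Na,1,1
KCl,311.8,74.55,K,1,1
CaCl2,116.6,110.98,Ca,1,2
MgCl2,28.64,95.21,Mg,1,2
MgSO4,48.84,120.37,Mg,1,2
Fe(NO3)3.9H2O,0.05,404.0,Fe,1,3
FeSO4.7H2O,0.417,278.01,Fe,1,2
ZnSO4.7H2O,0.432,287.56,Zn,1,2
CuSO4.5H2O,0.0013,249.68,Cu,1,2
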