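# Published per-land-use contamination factors (CF), degree of
# contamination (C_d) and contamination level for the Jashore urban-soil
# survey; validation reference for the index chain.
land_use,As,Cd,Pb,Cr,Ni,Cu,c_d,level
PA,1.74,2.83,0.34,0.95,0.59,0.58,7.03,Moderate
PG,1.61,2.58,0.43,0.74,0.71,0.62,6.69,Moderate
M,1.05,3.26,1.22,1.19,0.42,1.19,8.33,Moderate
BF,2.07,3.62,1.44,0.98,0.94,1.24,10.29,Considerable
IA,1.36,4.03,3.92,0.72,0.75,0.71,11.49,Considerable
PP,1.39,3.14,0.77,0.82,0.46,1.05,7.63,Moderate
MW,2.32,6.84,3.22,0.82,2.34,4.62,20.16,High
BS,1.42,4.16,1.39,1.00,0.65,1.56,10.18,Considerable
PS,1.58,3.14,0.47,0.92,0.78,0.97,7.86,Moderate
RA,1.15,2.01,0.20,0.14,0.46,0.46,4.42,Low
WDA,1.27,4.15,1.49,0.94,0.86,1.22,9.93,Moderate
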