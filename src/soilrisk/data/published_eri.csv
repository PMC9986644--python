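# Published per-land-use potential ecological risk factors (E_r), summed
# potential ecological risk (PERI) and risk level for the Jashore
# urban-soil survey; validation reference for the ecological-risk chain.
land_use,As,Cd,Pb,Cr,Ni,Cu,peri,level
PA,17.46,85.0,1.69,1.89,3.54,2.90,112.49,Moderate
PG,16.14,77.5,2.15,1.48,4.29,3.11,104.67,Moderate
M,10.52,97.75,6.12,2.38,2.53,5.95,125.25,Moderate
BF,20.74,108.63,7.22,1.96,5.64,6.20,150.39,Considerable
IA,13.64,120.75,19.59,1.44,4.50,3.56,163.49,Considerable
PP,13.90,94.25,3.87,1.64,2.74,5.27,121.68,Moderate
MW,23.24,205.13,16.09,1.63,14.05,23.09,283.22,Very high
BS,14.20,124.67,6.97,2.01,3.89,7.79,159.53,Considerable
PS,15.85,94.25,2.37,1.85,4.66,4.85,123.84,Moderate
RA,11.57,60.25,1.02,0.29,2.77,2.32,78.23,Moderate
WDA,12.80,124.40,7.44,1.88,5.18,6.09,157.78,Considerable
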