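# Published per-land-use geoaccumulation index (Igeo) values for the
# Jashore urban-soil survey; validation reference for the index chain.
land_use,As,Cd,Pb,Cr,Ni,Cu
PA,0.22,0.92,-2.15,-0.66,-1.34,-1.37
PG,0.11,0.78,-1.80,-1.01,-1.07,-1.27
M,-0.51,1.12,-0.29,-0.34,-1.83,-0.33
BF,0.47,1.27,-0.06,-0.61,-0.67,-0.27
IA,-0.14,1.42,1.39,-1.06,-1.00,-1.07
PP,-0.11,1.07,-0.95,-0.87,-1.72,-0.51
MW,0.63,2.19,1.10,-0.88,0.64,1.62
BS,-0.08,1.47,-0.10,-0.58,-1.21,0.05
PS,0.08,1.07,-1.66,-0.70,-0.95,-0.63
RA,-0.37,0.42,-2.87,-3.39,-1.70,-1.69
WDA,-0.23,1.47,-0.01,-0.67,-0.80,-0.30
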