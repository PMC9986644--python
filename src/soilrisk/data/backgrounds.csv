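# Pre-industrial (background) soil concentrations, mg/kg dry weight,
# for the Jashore district study area.
element,background
As,4.90
Cd,0.30
Pb,20.00
Cr,41.00
Ni,22.00
Cu,27.00
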