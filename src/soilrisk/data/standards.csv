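# Regulatory soil-quality standards, mg/kg dry weight.
# DSQS: Dutch soil quality standard; CSQS: Canadian environmental quality
# guideline; TRV: toxicity reference value; ASQS: Australian soil quality
# standard.
standard,As,Cd,Pb,Cr,Ni,Cu
DSQS,29.00,0.80,85.00,100.00,35.00,36.00
CSQS,12.00,1.40,70.00,64.00,50.00,63.00
TRV,6.00,0.60,31.00,26.00,16.00,16.00
ASQS,20.00,3.00,300.00,50.00,60.00,60.00
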