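# Hakanson biological toxic-response factors (dimensionless).
element,toxic_response
As,10
Cd,30
Pb,5
Cr,2
Ni,6
Cu,5
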