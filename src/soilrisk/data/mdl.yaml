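# Method detection limits (mg/kg) for the AAS determinations. As and Cd
# are instrument-specific values; the survey reports only a collective
# range of 0.013-0.070 for Cr, Cu, Ni and Pb, so their default is the
# mid-range 0.04. Used for the PMF uncertainty rules; configurable.
As: 3.0e-4
Cd: 4.0e-3
Pb: 4.0e-2
Cr: 4.0e-2
Ni: 4.0e-2
Cu: 4.0e-2
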