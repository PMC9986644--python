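# Default toxicity constants: reference doses (RfD, mg/kg/day) and cancer
# slope factors (CSF, (mg/kg/day)^-1) per exposure route, drawn from
# standard USEPA compilations (IRIS / regional screening tables). Routes
# without an entry fall back to the ingestion (oral) value and the report
# flags the fallback; every entry is overridable via a user file.
# Elements with no CSF are not assessed for carcinogenic risk.
rfd:
  As: {ingestion: 3.0e-4}
  Cd: {ingestion: 1.0e-3}
  Pb: {ingestion: 3.5e-3}
  Cr: {ingestion: 3.0e-3}
  Ni: {ingestion: 2.0e-2}
  Cu: {ingestion: 4.0e-2}
csf:
  As: {ingestion: 1.5}
  Cd: {ingestion: 6.1}
  Pb: {ingestion: 8.5e-3}
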