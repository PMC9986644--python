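# Classification schemes for the pollution and risk indices. Bins are
# lower-inclusive: a value equal to a boundary falls in the upper bin.
# "lower" is the domain minimum; values below it are rejected.
# *_study schemes are reconstructions of the categories used in the
# Jashore survey report, whose C_d and PERI labels are inconsistent with
# the classical Hakanson cutoffs (see docs/methods.md).
cf_hakanson:
  lower: 0
  boundaries: [1, 3, 6]
  labels: [Low, Moderate, Considerable, Very high]
cd_hakanson:
  lower: 0
  boundaries: [8, 16, 32]
  labels: [Low, Moderate, Considerable, Very high]
cd_study:
  lower: 0
  boundaries: [6, 10, 20]
  labels: [Low, Moderate, Considerable, High]
igeo_muller:
  lower: -.inf
  boundaries: [0, 1, 2, 3, 4, 5]
  labels:
    - Unpolluted
    - Unpolluted to moderately polluted
    - Moderately polluted
    - Moderately to heavily polluted
    - Heavily polluted
    - Heavily to extremely polluted
    - Extremely polluted
pli:
  lower: 0
  boundaries: [1]
  labels: [Baseline, Deteriorating]
er_hakanson:
  lower: 0
  boundaries: [40, 80, 160, 320]
  labels: [Low, Moderate, Considerable, High, Very high]
peri_hakanson:
  lower: 0
  boundaries: [150, 300, 600]
  labels: [Low, Moderate, Considerable, Very high]
peri_study:
  lower: 0
  boundaries: [150, 200]
  labels: [Moderate, Considerable, Very high]
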