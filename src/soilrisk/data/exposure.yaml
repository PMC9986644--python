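# USEPA default exposure parameters for incidental soil ingestion, dermal
# contact and dust inhalation, child and adult receptors.
# Units: body_weight kg; exposure_frequency days/year; exposure_duration
# years; ingestion_rate mg/day; inhalation_rate m^3/day; skin_area cm^2;
# adherence_factor mg/cm^2; dermal_absorption, dermal_exposure_ratio
# dimensionless; particulate_emission_factor m^3/kg; conversion_factor
# kg/mg; lifetime_years years (fixes the carcinogenic averaging time at
# 365 * lifetime_years days; the non-carcinogenic averaging time is
# 365 * exposure_duration days).
child:
  body_weight: 15.0
  exposure_frequency: 350.0
  exposure_duration: 6.0
  ingestion_rate: 200.0
  inhalation_rate: 10.0
  skin_area: 2100.0
  adherence_factor: 0.2
  dermal_absorption: 0.1
  dermal_exposure_ratio: 0.61
  particulate_emission_factor: 1.3e+9
  conversion_factor: 1.0e-6
  lifetime_years: 70.0
adult:
  body_weight: 70.0
  exposure_frequency: 350.0
  exposure_duration: 30.0
  ingestion_rate: 100.0
  inhalation_rate: 20.0
  skin_area: 5800.0
  adherence_factor: 0.07
  dermal_absorption: 0.1
  dermal_exposure_ratio: 0.61
  particulate_emission_factor: 1.3e+9
  conversion_factor: 1.0e-6
  lifetime_years: 70.0
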