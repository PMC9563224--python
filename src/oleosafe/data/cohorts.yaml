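# Exposure cohorts for the bundled reproduction: body weights for 8-, 18-
# and 30-year-olds and the matching reference oil ingestion rates (g/day).
# Exposure frequency 365 days/year and averaging time = ED x 365 days make
# the CDI prefactor cancel, so CDI = C x IR / BW.
cohorts:
  - label: 8y
    age_years: 8
    body_weight: 26
    ingestion_rate: 0.61
  - label: 18y
    age_years: 18
    body_weight: 62
    ingestion_rate: 1.46
  - label: 30y
    age_years: 30
    body_weight: 70
    ingestion_rate: 1.65
targets:
  hi: 0.99
  cancer_risk: 1.0e-4
unit_mode: paper
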