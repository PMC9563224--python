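# Codex Alimentarius identity/quality rules for sunflower oil.
parameters:
  peroxide_index:
    kind: maximum
    max: 20
    units: mEq/kg
    provenance: "Codex standard for named vegetable oils"
  iodine_index:
    kind: range
    low: 118
    high: 141
    units: g I2/100 g
    provenance: "Codex standard for named vegetable oils"
  acidity_index:
    kind: maximum
    max: 4.0
    units: mg KOH/g
    provenance: "Codex standard for named vegetable oils"
  saponification_index:
    kind: range
    low: 184
    high: 196
    units: mg KOH/g
    provenance: "Codex standard for named vegetable oils"
  relative_density:
    kind: range
    low: 0.92
    high: 0.93
    units: "20C"
    provenance: "Codex standard for named vegetable oils"
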