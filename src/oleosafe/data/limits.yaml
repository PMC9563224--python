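# Regulatory / reference values per element.
#   fao_who       : concentration limit in oil, mg/kg
#   dri_ai        : dietary reference intake or adequate intake, mg/day, by cohort
#   rfd           : oral reference dose, mg per kg body weight per day
#   slope_factor  : cancer slope factor, (mg/kg/day)^-1
# provenance strings record the citation context of the bundled numbers.
elements:
  Cr:
    fao_who: 0.002
    rfd: 0.003
    slope_factor: 0.5
    provenance: "FAO/WHO oil limit; US EPA oral RfD and SF"
    dri_ai:
      children-8y: 0.015
      male-18y: 0.035
      male-30y: 0.035
      female-18y: 0.024
      female-30y: 0.025
      pregnancy-18y: 0.029
      pregnancy-30y: 0.030
      lactation-18y: 0.044
      lactation-30y: 0.045
  Mn:
    fao_who: 3.00
    rfd: 0.14
    provenance: "FAO/WHO oil limit; US EPA oral RfD; DRI adequate intakes"
    dri_ai:
      children-8y: 1.5
      male-18y: 2.2
      male-30y: 2.3
      female-18y: 1.6
      female-30y: 1.8
      pregnancy-18y: 2.0
      pregnancy-30y: 2.0
      lactation-18y: 2.6
      lactation-30y: 2.6
  Fe:
    fao_who: 14.00
    rfd: 0.7
    provenance: "FAO/WHO oil limit; US EPA provisional RfD; DRI RDAs"
    dri_ai:
      children-8y: 10
      male-18y: 11
      male-30y: 8
      female-18y: 15
      female-30y: 18
      pregnancy-18y: 27
      pregnancy-30y: 27
      lactation-18y: 10
      lactation-30y: 9
  Cu:
    fao_who: 0.90
    rfd: 0.04
    provenance: "FAO/WHO oil limit; US EPA oral RfD; DRI RDAs"
    dri_ai:
      children-8y: 0.44
      male-18y: 0.89
      male-30y: 0.9
      female-18y: 0.89
      female-30y: 0.9
      pregnancy-18y: 1.0
      pregnancy-30y: 1.0
      lactation-18y: 1.3
      lactation-30y: 1.3
  Zn:
    fao_who: 15.00
    rfd: 0.3
    provenance: "FAO/WHO oil limit; US EPA oral RfD; DRI RDAs"
    dri_ai:
      children-8y: 5
      male-18y: 11
      male-30y: 11
      female-18y: 9
      female-30y: 8
      pregnancy-18y: 12
      pregnancy-30y: 11
      lactation-18y: 13
      lactation-30y: 12
  Al:
    fao_who: 5.00
    rfd: 1.0
    provenance: "FAO/WHO oil limit; provisional oral RfD; no DRI established"
    dri_ai: {}
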