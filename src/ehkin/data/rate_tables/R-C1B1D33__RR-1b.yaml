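variant: R-C1B1D33
substrate: RR-1b
provenance: kinetic parameter table, R-C1B1D33 / RR-1b row
values:
  kcat:
    value: 0.38
    se: 0.09
  Km:
    value: 190
    se: 60
  kcat_over_Km:
    value: 2.0
    se: 0.1
qualifiers: {}
regioselectivity: meso product
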