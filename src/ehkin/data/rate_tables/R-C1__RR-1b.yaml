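variant: R-C1
substrate: RR-1b
provenance: kinetic parameter table, R-C1 / RR-1b row
values:
  kcat:
    value: 12
    se: 0.5
  Km:
    value: 20
    se: 2
  kcat_over_Km:
    value: 610
    se: 40
  K_S:
    value: 13
    se: 17
  k2:
    value: 85
    se: 3
  k_m2:
    value: 22
    se: 40
  k3:
    value: 28
    se: 0.2
    note: experimentally determined in a single-turnover experiment
qualifiers: {}
regioselectivity: meso product
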