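variant: R-C1
substrate: SS-1b
provenance: kinetic parameter table, R-C1 / SS-1b row
values:
  kcat:
    value: 4.4
    se: 0.09
  Km:
    value: 1.3
    se: 0.09
  kcat_over_Km:
    value: 3300
    se: 20
  K_S:
    value: 16
    se: 5
  k2:
    value: 120
    se: 9
  k_m2:
    value: 4.2
    se: 6
  k3:
    value: 5.4
    se: 0.01
    note: experimentally determined in a single-turnover experiment
qualifiers: {}
regioselectivity: meso product
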