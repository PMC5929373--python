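variant: R-C1B1
substrate: SS-1b
provenance: kinetic parameter table, R-C1B1 / SS-1b row
values:
  kcat:
    value: 4.0
    se: 0.09
  Km:
    value: 16
    se: 0.9
  kcat_over_Km:
    value: 250
    se: 0.09
  K_S:
    value: 21
    se: 10
  k2:
    value: 8.9
    se: 1
  k_m2:
    value: 5.1
    se: 0.08
  k3:
    value: 3.0
    se: 0.01
    note: experimentally determined in a single-turnover experiment
qualifiers: {}
regioselectivity: meso product
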