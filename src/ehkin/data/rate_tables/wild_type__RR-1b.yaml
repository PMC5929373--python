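variant: wild_type
substrate: RR-1b
provenance: kinetic parameter table, wild_type / RR-1b row
values:
  kcat:
    value: 17
    se: 0.5
  Km:
    value: 16
    se: 1
  kcat_over_Km:
    value: 1100
    se: 50
  K_S:
    value: 7.8
    se: 13
  k2:
    value: 180
    se: 100
  k_m2:
    value: 13
    se: 10
  k3:
    value: 42
    se: 0.2
    note: experimentally determined in a single-turnover experiment
qualifiers: {}
regioselectivity: meso product
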