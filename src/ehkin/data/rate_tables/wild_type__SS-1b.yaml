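variant: wild_type
substrate: SS-1b
provenance: kinetic parameter table, wild_type / SS-1b row
values:
  kcat:
    value: 4.0
    se: 0.06
  Km:
    value: 1.0
    se: 0.08
  kcat_over_Km:
    value: 3900
    se: 200
  K_S:
    value: 5.5
    se: 0.9
  k2:
    value: 23
    se: 0.7
  k_m2:
    value: 4.5
    se: 0.8
  k3:
    value: 3.9
    se: 0.005
    note: experimentally determined in a single-turnover experiment
qualifiers: {}
regioselectivity: meso product
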