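variant: R-C1
substrate: SS-1a
provenance: kinetic parameter table, R-C1 / SS-1a row
values:
  kcat:
    value: 65
    se: 2
  Km:
    value: 110
    se: 10
  kcat_over_Km:
    value: 560
    se: 40
  K_S:
    value: 1600
    se: 900
  k2:
    value: 2100
    se: 600
  k_m2:
    value: 240
    se: 60
    note: calculated from the steady-state kcat expression and the measured sum k_m2
      + k3
  k3:
    value: 75
    se: 30
    note: calculated from the steady-state kcat expression and the measured sum k_m2
      + k3
  sum_k5_km5:
    value: 44
    se: 50
qualifiers: {}
regioselectivity: 99% C1
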