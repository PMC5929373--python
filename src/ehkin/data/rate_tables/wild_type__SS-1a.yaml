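variant: wild_type
substrate: SS-1a
provenance: kinetic parameter table, wild_type / SS-1a row
values:
  kcat:
    value: 63
    se: 3
    note: previously reported measurement
  Km:
    value: 77
    se: 10
    note: previously reported measurement
  kcat_over_Km:
    value: 820
    se: 100
    note: previously reported measurement
  K_S:
    value: 470
    se: 100
    note: previously reported measurement
  k2:
    value: 370
    se: 20
    note: previously reported measurement
  k_m2:
    value: 170
    se: 20
    note: calculated from the steady-state kcat expression and the measured sum k_m2
      + k3
  k3:
    value: 110
    se: 10
    note: calculated from the steady-state kcat expression and the measured sum k_m2
      + k3
  sum_k5_km5:
    value: 32
    se: 2
    note: previously reported measurement
qualifiers: {}
regioselectivity: 99% C1
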