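variant: R-C1B1
substrate: SS-1a
provenance: kinetic parameter table, R-C1B1 / SS-1a row
values:
  kcat:
    value: 31
    se: 1
  Km:
    value: 240
    se: 20
  kcat_over_Km:
    value: 130
    se: 6
  K_S:
    value: 2700
    se: 2000
  k2:
    value: 1400
    se: 800
  k_m2:
    value: 10
    se: 30
    note: calculated from the steady-state kcat expression and the measured sum k_m2
      + k3
  k3:
    value: 32
    se: 20
    note: calculated from the steady-state kcat expression and the measured sum k_m2
      + k3
qualifiers: {}
regioselectivity: 99% C1
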