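variant: R-C1B1D33
substrate: SS-1a
provenance: kinetic parameter table, R-C1B1D33 / SS-1a row
values:
  kcat:
    value: 79
    se: 5
  Km:
    value: 410
    se: 40
  kcat_over_Km:
    value: 190
    se: 20
  K_S:
    value: 6500
    se: 6000
  k2:
    value: 2600
    se: 2000
  k_m2:
    value: 74
    se: 90
    note: calculated from the steady-state kcat expression and the measured sum k_m2
      + k3
  k3:
    value: 84
    se: 90
    note: calculated from the steady-state kcat expression and the measured sum k_m2
      + k3
qualifiers: {}
regioselectivity: 99% C1
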