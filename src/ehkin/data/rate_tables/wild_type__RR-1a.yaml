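variant: wild_type
substrate: RR-1a
provenance: kinetic parameter table, wild_type / RR-1a row
values:
  kcat:
    value: 4.7
    se: 0.7
    note: previously reported measurement
  Km:
    value: 490
    se: 100
    note: previously reported measurement
  kcat_over_Km:
    value: 9.7
    se: 2
    note: previously reported measurement
  sum_k5_km5:
    value: 8.1
    se: 3
    note: previously reported measurement
qualifiers: {}
regioselectivity: 55% C1
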