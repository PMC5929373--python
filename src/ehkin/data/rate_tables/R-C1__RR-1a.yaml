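variant: R-C1
substrate: RR-1a
provenance: kinetic parameter table, R-C1 / RR-1a row
values:
  kcat:
    value: 25
    se: 4
  Km:
    value: 3300
    se: 10
  kcat_over_Km:
    value: 7.7
    se: 0.2
  sum_k5_km5:
    value: 48
    se: 70
qualifiers: {}
regioselectivity: 66% C1
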