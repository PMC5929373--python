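variant: R-C1B1D33E6
substrate: SS-1b
provenance: kinetic parameter table, R-C1B1D33E6 / SS-1b row
values:
  kcat:
    value: 0.42
    se: 0.09
  Km:
    value: 110
    se: 30
  kcat_over_Km:
    value: 3.1
    se: 0.2
qualifiers:
  k2: too_fast
regioselectivity: meso product
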