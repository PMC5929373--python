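variant: R-C1B1D33
substrate: SS-1b
provenance: kinetic parameter table, R-C1B1D33 / SS-1b row
values:
  kcat:
    value: 12
    se: 0.7
  Km:
    value: 65
    se: 6
  kcat_over_Km:
    value: 180
    se: 6
qualifiers:
  k2: too_fast
regioselectivity: meso product
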