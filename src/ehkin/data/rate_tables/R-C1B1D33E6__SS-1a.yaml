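variant: R-C1B1D33E6
substrate: SS-1a
provenance: kinetic parameter table, R-C1B1D33E6 / SS-1a row
values:
  kcat_over_Km:
    value: 10
    se: 0.2
qualifiers:
  kcat: not_saturating
  Km: not_saturating
regioselectivity: 99% C1
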