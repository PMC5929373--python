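variant: R-C1B1D33
substrate: RR-1a
provenance: kinetic parameter table, R-C1B1D33 / RR-1a row
values:
  kcat_over_Km:
    value: 0.25
    se: 0.01
qualifiers:
  kcat: not_saturating
  Km: not_saturating
regioselectivity: 91% C2
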