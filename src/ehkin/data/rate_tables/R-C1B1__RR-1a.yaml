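variant: R-C1B1
substrate: RR-1a
provenance: kinetic parameter table, R-C1B1 / RR-1a row
values:
  kcat:
    value: 0.92
    se: 0.4
  Km:
    value: 3400
    se: 200
  kcat_over_Km:
    value: 0.26
    se: 0.01
qualifiers: {}
regioselectivity: 89% C2
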