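variant: R-C1B1D33E6
substrate: RR-1b
provenance: kinetic parameter table, R-C1B1D33E6 / RR-1b row
values: {}
qualifiers:
  kcat_over_Km: upper_bound:0.1
regioselectivity: meso product
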