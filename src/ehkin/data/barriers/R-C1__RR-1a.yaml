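variant: R-C1
substrate: RR-1a
temperature_K: 303.15
provenance: published EVB barrier table, R-C1 / RR-1a; these simulated values are
  consumed as inputs, never recomputed
experimental:
  dG_alk: null
  dG_hyd: 15.8
  dG_hyd_source: kcat
modes:
  mode1:
    C1:
      dG_alk: 10.9
      se_alk: 0.3
      dG0_alk: -16.8
      se0_alk: 0.5
      dG_hyd: 16.1
      se_hyd: 0.3
      dG0_hyd: 9.7
      se0_hyd: 0.4
    C2:
      dG_alk: 9.8
      se_alk: 0.4
      dG0_alk: -24.7
      se0_alk: 0.7
      dG_hyd: 14.1
      se_hyd: 0.2
      dG0_hyd: 6.9
      se0_hyd: 0.3
  mode2:
    C1:
      dG_alk: 16.3
      se_alk: 0.3
      dG0_alk: -8.7
      se0_alk: 0.5
      dG_hyd: 14.3
      se_hyd: 0.2
      dG0_hyd: 6.6
      se0_hyd: 0.3
    C2:
      dG_alk: 15.5
      se_alk: 0.4
      dG0_alk: -7.6
      se0_alk: 0.4
      dG_hyd: 21.6
      se_hyd: 0.2
      dG0_hyd: 15.2
      se0_hyd: 0.2
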