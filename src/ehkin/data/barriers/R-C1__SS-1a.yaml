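variant: R-C1
substrate: SS-1a
temperature_K: 303.15
provenance: published EVB barrier table, R-C1 / SS-1a; these simulated values are
  consumed as inputs, never recomputed
experimental:
  dG_alk: 13.1
  dG_alk_source: k2
  dG_hyd: 15.1
  dG_hyd_source: k3
modes:
  mode1:
    C1:
      dG_alk: 9.9
      se_alk: 0.2
      dG0_alk: -22.7
      se0_alk: 0.3
      dG_hyd: 14.8
      se_hyd: 0.2
      dG0_hyd: 9.3
      se0_hyd: 0.3
    C2:
      dG_alk: 10.4
      se_alk: 0.4
      dG0_alk: -25.5
      se0_alk: 0.5
      dG_hyd: 19.6
      se_hyd: 0.3
      dG0_hyd: 14.3
      se0_hyd: 0.4
  mode2:
    C1:
      dG_alk: 16.0
      se_alk: 0.6
      dG0_alk: -10.5
      se0_alk: 0.7
      dG_hyd: 18.0
      se_hyd: 0.2
      dG0_hyd: 11.9
      se0_hyd: 0.3
    C2:
      dG_alk: 12.5
      se_alk: 0.6
      dG0_alk: -15.4
      se0_alk: 0.8
      dG_hyd: 24.7
      se_hyd: 0.2
      dG0_hyd: 20.0
      se0_hyd: 0.2
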