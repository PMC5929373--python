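variant: wild_type
substrate: SS-1a
temperature_K: 303.15
provenance: published EVB barrier table, wild_type / SS-1a; these simulated values
  are consumed as inputs, never recomputed
experimental:
  dG_alk: 14.2
  dG_alk_source: k2
  dG_hyd: 14.9
  dG_hyd_source: k3
modes:
  mode1:
    C1:
      dG_alk: 12.2
      se_alk: 0.4
      dG0_alk: -15.7
      se0_alk: 0.6
      dG_hyd: 16.5
      se_hyd: 0.2
      dG0_hyd: 11.6
      se0_hyd: 0.3
    C2:
      dG_alk: 13.3
      se_alk: 0.3
      dG0_alk: -21.1
      se0_alk: 0.4
      dG_hyd: 20.9
      se_hyd: 0.2
      dG0_hyd: 16.4
      se0_hyd: 0.3
  mode2:
    C1:
      dG_alk: 16.8
      se_alk: 0.5
      dG0_alk: -8.0
      se0_alk: 0.8
      dG_hyd: 18.7
      se_hyd: 0.3
      dG0_hyd: 13.6
      se0_hyd: 0.3
    C2:
      dG_alk: 13.8
      se_alk: 0.4
      dG0_alk: -13.0
      se0_alk: 0.6
      dG_hyd: 25.4
      se_hyd: 0.2
      dG0_hyd: 20.4
      se0_hyd: 0.2
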