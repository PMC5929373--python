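variant: wild_type
substrate: RR-1a
temperature_K: 303.15
provenance: published EVB barrier table, wild_type / RR-1a; these simulated values
  are consumed as inputs, never recomputed
experimental:
  dG_alk: null
  dG_hyd: 16.8
  dG_hyd_source: kcat
modes:
  mode1:
    C1:
      dG_alk: 15.1
      se_alk: 0.5
      dG0_alk: -10.1
      se0_alk: 0.5
      dG_hyd: 17.8
      se_hyd: 0.3
      dG0_hyd: 12.0
      se0_hyd: 0.4
    C2:
      dG_alk: 13.5
      se_alk: 0.7
      dG0_alk: -18.1
      se0_alk: 0.7
      dG_hyd: 18.1
      se_hyd: 0.3
      dG0_hyd: 12.3
      se0_hyd: 0.4
  mode2:
    C1:
      dG_alk: 17.7
      se_alk: 0.4
      dG0_alk: -6.5
      se0_alk: 0.6
      dG_hyd: 19.8
      se_hyd: 0.3
      dG0_hyd: 13.5
      se0_hyd: 0.4
    C2:
      dG_alk: 17.3
      se_alk: 0.3
      dG0_alk: -5.5
      se0_alk: 0.5
      dG_hyd: 24.2
      se_hyd: 0.2
      dG0_hyd: 18.7
      se0_hyd: 0.3
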