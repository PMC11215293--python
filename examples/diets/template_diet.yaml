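# Synthetic template showing the full diet schema (not a curated diet).
name: template
default_policy: unconstrained
lumen:
  glc__D_e: [-10, 1000]
  fru_e: [-5, 1000]
blood:
  # host-only: bounds on blood-side boundary reactions, by reaction id
  SINK_waste_b: [0, 1000]
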