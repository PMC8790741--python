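# Synthetic regeneration-phase study: two animals, four subsets including
# the dim/bright split of the regenerating CD16 compartment, all with slow
# blood exit (high continuous circulation).  Animal RMK2's 48 h infusion is
# masked (uninterpretable, e.g. extravasated), so its summaries are
# computed on the remaining three pulses by complete-case analysis.
name: depletion_like
seed: 1
burn_in_hours: 0.0
schedule:
  dose_ug_per_kg: 30.0
  pulses:
    - {time: 48.0, channel: AF647}
    - {time: 24.0, channel: AF594}
    - {time: 6.0, channel: AF488}
    - {time: 0.0833, channel: BV421}
animals:
  - {name: RMH1}
  - {name: RMK2, invalid_channels: [AF647]}
tissues:
  - {name: LN, sinusoidal: false}
subsets:
  - {name: CD56, exit_rate_blood: 0.5, return_rate_tissue: 0.3}
  - {name: DN, exit_rate_blood: 0.05, return_rate_tissue: 0.3}
  - {name: CD16dim, exit_rate_blood: 0.02, return_rate_tissue: 0.3}
  - {name: CD16bright, exit_rate_blood: 0.02, return_rate_tissue: 0.3}
cell_counts:
  CD56: {LN: 3000}
  DN: {LN: 3000}
  CD16dim: {LN: 3000}
  CD16bright: {LN: 3000}
analysis:
  lookbacks: [6.0, 24.0, 48.0]
  entry_rate_window: 6.0
  gate_quantile: 0.999
  label_efficiency: 1.0
  control_n: 5000
  comparisons: []
  holm: false
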