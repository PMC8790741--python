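# Synthetic single-infusion study: one animal given only the IVas pulse
# 5 minutes before harvest.  Supports IVas+/- separation; positional
# history beyond the harvest instant is indeterminate by design.
name: single_pulse
seed: 1
burn_in_hours: 48.0
schedule:
  dose_ug_per_kg: 30.0
  pulses:
    - {time: 0.0833, channel: BV421}
animals:
  - {name: RMZ1}
tissues:
  - {name: LN, sinusoidal: false}
subsets:
  - {name: CD56, exit_rate_blood: 0.5, return_rate_tissue: 0.3}
  - {name: DN, exit_rate_blood: 0.15, return_rate_tissue: 0.3}
  - {name: CD16, exit_rate_blood: 0.02, return_rate_tissue: 0.3}
cell_counts:
  CD56: {LN: 2000}
  DN: {LN: 2000}
  CD16: {LN: 2000}
analysis:
  lookbacks: [0.0833]
  entry_rate_window: null
  gate_quantile: 0.999
  label_efficiency: 1.0
  control_n: 5000
  comparisons: []
  holm: false
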