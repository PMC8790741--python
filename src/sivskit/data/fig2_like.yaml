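# Synthetic steady-state study: four animals on the 48 h / 24 h / 6 h /
# 5 min infusion schedule, three NK-like subsets whose blood exit rates
# decrease CD56 -> DN -> CD16, one non-sinusoidal lymph node tissue.
name: fig2_like
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
  - {name: RM1}
  - {name: RM2}
  - {name: RM3}
  - {name: RM4}
tissues:
  - {name: LN, sinusoidal: false}
subsets:
  - {name: CD56, exit_rate_blood: 0.5, return_rate_tissue: 0.3}
  - {name: DN, exit_rate_blood: 0.15, return_rate_tissue: 0.3}
  - {name: CD16, exit_rate_blood: 0.02, return_rate_tissue: 0.3}
cell_counts:
  CD56: {LN: 4000}
  DN: {LN: 4000}
  CD16: {LN: 4000}
analysis:
  lookbacks: [6.0, 48.0]
  entry_rate_window: 6.0
  gate_quantile: 0.999
  label_efficiency: 1.0
  control_n: 5000
  comparisons:
    - {metric: cc_6h, tissue: blood}
    - {metric: cc_48h, tissue: blood}
    - {metric: ivas_pos_fraction, tissue: LN}
    - {metric: tl_fraction, tissue: LN}
  holm: false
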