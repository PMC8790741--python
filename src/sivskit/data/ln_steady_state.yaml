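# Synthetic slow-exchange lymph node: a single subset whose stationary
# influx replaces 0.5% of the tissue pool per hour (the hourly influx as a
# fraction of the tissue pool equals the tissue return rate at
# stationarity), with the default tissue-acquired retention marker.
# Used for entry-rate recovery and marker-retention analyses.
name: ln_steady_state
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
tissues:
  - {name: LN, sinusoidal: false}
subsets:
  - name: DN
    exit_rate_blood: 0.02
    return_rate_tissue: 0.005
    marker_acquisition_rate: 1.0
    marker_loss_rate: 0.5
cell_counts:
  DN: {LN: 20000}
analysis:
  lookbacks: [6.0, 48.0]
  entry_rate_window: 6.0
  gate_quantile: 0.999
  label_efficiency: 1.0
  control_n: 5000
  comparisons: []
  holm: false
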