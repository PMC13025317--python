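grid:
  nx: 10
  ny: 6
model:
  kappa: 0.01
  amplitude: 0.01
  dt: 0.2
  normalization: zero-mean
sweep:
  frequencies: [0.001, 0.002, 0.004]
  transient_periods: 2
  measure_periods: 2
  settle_multiple: 10.0
seed: 1
output: quick_sweep.csv
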