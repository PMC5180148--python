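# Eight-point, two-variable walkthrough: one window, strict binning.
input:
  path: examples/worked_example.csv
  format: csv
  time_column: time
size_of_state:
  mode: explicit
  values: [0.5, 1.0]
window:
  width: 8
  increment: 1
tightening:
  mode: strict
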