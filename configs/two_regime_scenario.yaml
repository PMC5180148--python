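# Synthetic benchmark: two stationary regimes with a mean step at t = 61.
seed: 42
variables: [y1, y2]
regimes:
  - {start: 1, end: 60, means: [0.0, 0.0], sds: [0.1, 0.1]}
  - {start: 61, end: 120, means: [10.0, 10.0], sds: [0.1, 0.1]}
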