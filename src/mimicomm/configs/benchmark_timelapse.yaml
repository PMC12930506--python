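# Time-lapse benchmark: 5 samples imaged every 15 min over 5 h.
version: 1
extends: defaults
seed: 42
layout:
  kind: benchmark_random
  n_samples: 5
  n_controls: 0
  total_count_range: [150, 400]
  fraction_alpha: [4.0, 2.0, 2.0]
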