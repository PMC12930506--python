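# End point benchmark: 29 dual-sender-type samples with mimic counts
# spanning ~30-500 plus 5 sender-free control samples for fold changes.
version: 1
extends: defaults
seed: 42
layout:
  kind: benchmark_random
  n_samples: 29
  n_controls: 5
  total_count_range: [30, 500]
  fraction_alpha: [4.0, 2.0, 2.0]   # Dirichlet over receiver/STAR/trigger
  control_counts:
    receiver: 100
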