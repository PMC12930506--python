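# Central-sender benchmark: dual senders in a central patch surrounded by
# receivers out to ~2.1 mm, for propagation kymographs.
version: 1
extends: defaults
seed: 7
layout:
  kind: central
  droplet_radius: 2.1
  patch_radius: 0.5
  n_senders: 30
  n_receivers: 100
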