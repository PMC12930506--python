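# Default parameterization of the distributed RNA AND-gate model.
version: 1
seed: 42
gate:
  beta: 10.0          # max reporter synthesis rate, a.u./min
  alpha_term: 0.286   # terminator read-through leak (no STAR)
  alpha_toe: 0.03     # toehold leak (no trigger)
  K_S: 10.0           # STAR half-activation, field units
  K_T: 10.0           # trigger half-activation, field units
  n_S: 2.0
  n_T: 2.0
  tau_RNA: 17.0       # min
  tau_res: 120.0      # TXTL resource lifetime, min
  k_tx: 1.0
species:
  STAR:
    D: 8.48e-5        # mm^2/s
    tau: 1020.0       # s (~17 min)
    onset_delay: 15.0 # min
  trigger:
    D: 6.49e-5
    tau: 1020.0
    onset_delay: 15.0
layout:
  kind: random
  droplet_radius: 1.5   # mm (~5 uL sandwiched droplet)
  counts:
    receiver: 200
    star_sender: 60
    trigger_sender: 60
    dual_sender: 0
  diameter_range: [60.0, 80.0]  # um
  load_cv: 0.35
simulate:
  t_end: 300.0        # min (5 h)
  frame_interval: 15.0
  internal_dt: 5.0
  escape_fraction: 0.1   # reporter fraction escaping into the shared medium
  tau_mix: 120.0         # mixing lag of the escaped pool, min
  tau_leak: 180.0        # build-up time of basal leak synthesis, min
render:
  enabled: false
  pixel_size: 4.0     # um/px
  read_sigma: 5.0
  gain: 0.5
analysis:
  radius_grid: [200.0, 1200.0, 100.0]  # start, stop, step (um)
  chosen_radius: 600.0
  span: 0.5
  edge_correction: false
  min_receivers: 5
calibration:
  loading_efficiency: 0.70
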