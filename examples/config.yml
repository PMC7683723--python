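# Full synthetic-ensemble run: simulate a 15-piece ensemble and analyze it.
seed: 1
analysis:
  max_lag: 16        # Granger model order, seconds
  alpha: 0.05
  n_surrogates: 100  # time-scrambled draws per pair
simulation:
  n_musicians: 15
  n_intention_musicians: 12
  duration_s: 1159
  segmentation_boundaries: [0, 225, 270, 405, 535, 750, 885, 980, 1159]
  occupancy_target: 0.6
window_halfwidth_s: 16
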