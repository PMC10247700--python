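# Desk-scale end-to-end experiment config for `voxenc run`.
# A sibling file can reuse this via `include: experiment.yaml` and override
# individual keys.
scenario: hierarchical-brain
scale:
  resolution: 24
  n_train: 320
  n_shared: 80
  voxels_per_area: 10
  noise_sd: 0.7
  n_repeats: 3
  n_sessions: 4
fit:
  epochs: 150
  patience: 20
  polish_epochs: 150
  batch_size: 25
  lr: 0.01
  head_lr: 0.03
  dropout: 0.05
  prefilter: gabor-energy
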