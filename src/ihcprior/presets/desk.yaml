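# Desk-scale recipe: full pipeline on one CPU in minutes
backbone: small_cnn
patch_size: 32
feature_channels: 32
train:
  epochs: 30
  lr: 1.0e-3
  momentum: 0.9
  weight_decay: 1.0e-4
  lr_drop_factor: 0.1
  lr_milestones: [0.5, 0.75]
  batch_size_train: 32
  batch_size_eval: 64
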