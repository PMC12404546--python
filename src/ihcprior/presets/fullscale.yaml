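# Full-scale training recipe (reference settings)
backbone: resnet18
patch_size: 256
feature_channels: 512
train:
  epochs: 300
  lr: 1.0e-5
  momentum: 0.9
  weight_decay: 1.0e-4
  lr_drop_factor: 0.1
  lr_milestones: [0.5, 0.75]
  batch_size_train: 32
  batch_size_eval: 32
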