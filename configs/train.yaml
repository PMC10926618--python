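# Full-scale recipe (published protocol); see docs/methods.md
model:
  in_channels: 1
  num_classes: 6
  encoder_widths: [32, 64, 128, 256, 512]
  ppm_bins: [1, 2, 3, 6]
  ppm_enabled: true
  ag_enabled: true
  decode_mode: DS
train:
  lr: 0.0001
  lr_decay_factor: 0.9
  decay_epochs: [100, 150]
  batch_size: 16
  epochs: 300
  image_size: 256
  loss: lovasz
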