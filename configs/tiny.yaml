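# CPU-scale smoke configuration (64x64 phantoms, tiny widths)
model:
  encoder_widths: [8, 16, 32, 64, 128]
  ppm_bins: [1, 2, 3, 4]
  decode_mode: DS
train:
  lr: 0.001
  batch_size: 8
  epochs: 40
  image_size: 64
  val_fraction: 0.0
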