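# Clinical-study protocol: 224x224 input, ViT-Small/16 encoder with the
# [256, 128, 64, 32] decoder (23 M trainable parameters), Adam at 1e-4,
# batch 16, 40 epochs, 5-fold cross-validation, boundary-aware Dice loss.
train:
  learning_rate: 1.0e-4
  batch_size: 16
  epochs: 40
  folds: 5
  optimizer: adam
  seed: 0
  apply_preprocess: true
  threshold: 0.5
model:
  image_size: 224
  patch_size: 16
  embed_dim: 384
  depth: 12
  num_heads: 6
  mlp_ratio: 4.0
  decoder_channels: [256, 128, 64, 32]
loss:
  lambda_boundary: 1.0
  epsilon: 1.0e-6
preprocess:
  nlm_strength: 0.08
  nlm_patch: 7
  nlm_search: 21
  clahe_clip: 2.0
  clahe_tiles: [8, 8]
  unsharp_sigma: 1.0
  unsharp_amount: 1.0
postprocess:
  dilate_kernel: 3
  blur_sigma: 1.0
  canny_low: 50
  canny_high: 150
  edge_dilate_kernel: 3
  min_contour_area: 20
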