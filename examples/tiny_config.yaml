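# CPU-sized configuration: the desk-scale network and training recipe.
# Full-scale values (window 128, hidden 768, 12 layers/heads, N_i = N_s = 10)
# are the built-in defaults; everything here overrides toward a run that
# finishes in minutes on one CPU.

phantom:
  grid_size: 64
  n_satellites: 2
  cavity: true

unetr:
  window_edge: 32
  patch_edge: 16
  hidden_dim: 64
  mlp_dim: 128
  num_heads: 4
  num_layers: 2
  skip_layers: [1, 2]
  feature_size: 8
  dropout_rate: 0.05

train:
  n_images_per_batch: 2
  n_crops_per_image: 4
  crop_edges: [32, 32, 32]
  learning_rate: 1.0e-4
  weight_decay: 1.0e-5
  epochs: 30
  val_interval: 2

augmentation:
  flip_rot_prob_per_axis: 0.25
  intensity_shift_prob: 0.5
  intensity_shift_magnitude: 0.1
  gamma_prob: 0.8
  gamma_range: [0.5, 2.0]
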