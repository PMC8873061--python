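# Minimal end-to-end configuration: short procedures, tiny models.
# Runs the full pipeline (simulate -> emit -> train -> segment -> evaluate)
# in well under a minute on one CPU core.
seed: 7
n_train: 2
n_val: 1
n_test: 1
segment_mode: sync
mode_filter_width: 31

sim:
  phase_mean_s: [120, 260, 320, 60, 120]
  phase_sd_s: [20, 40, 50, 10, 20]
  transition_range_s: [10, 20]
  p_pause: 0.0
  fps: 2.4

emitter:
  feature_dim: 16
  class_separation: 3.0
  noise_sd: 1.0
  fine_accuracy: 0.69
  error_burst_len: 8.0

model:
  arch: lstm_seq2seq
  window_len: 40
  out_len: 40
  shift: 0
  feature_dim: 16
  d_model: 16
  lstm_layers: 1

train:
  strategy: noised
  noise_rate: 0.4
  windows_per_video: 12
  epochs: 3
  lr: 0.003
  lr_decay: 0.8
  lr_decay_every: 2
  validations_per_epoch: 2
  val_windows_per_video: 4
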