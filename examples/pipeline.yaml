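# Full pipeline on a small simulated field of view.
# Run with: filmspec run --config examples/pipeline.yaml
seed: 3
output_dir: filmspec_run

stages:
  simulate: true
  calibrate: true
  denoise: true
  segment: true
  unmix: true
  profile: true

simulate:
  shape: [48, 48]
  n_frames: 64
  n_organelles: 8
  noise_sigma: 0.2
  noise_corr_len_px: 3
  noise_axis: row

calibrate:
  smooth_window: 3
  exclude_bands: [[1380, 1480]]

denoise:
  base_channels: 4
  epochs: 6
  steps_per_epoch: 8
  patch_shape: [24, 24, 16]

segment:
  min_size_px: 4
  connectivity: 8

unmix:
  lambda: auto
  max_iter: 30

profile:
  ratio_thresholds: median
  chord_threshold: 0.5
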