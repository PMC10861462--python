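# Default desk-scale pipeline configuration.
# All analysis thresholds are surfaced here by name.

simulate:
  groups:
    - {label: TD, n: 15, motion_level: 0.13}
    - {label: ASD, n: 15, motion_level: 0.18}
    - {label: ADHD-C, n: 15, motion_level: 0.22}
    - {label: ADHD-I, n: 15, motion_level: 0.33}
  n_voxels: 2000
  k: 17
  t_raw: 180
  tr: 2.0
  snr: 2.0
  format: npz
  fnc_effects: []
  clinical_links: []

preprocess:
  drop: 10
  band: [0.01, 0.1]
  fd_thresh: 0.5
  voxel_size_mm: 3.0

netmap:
  k: 17
  beta: 1.0e-5
  alpha: 0.1
  repeats: 5      # desk-scale default; the full-scale analysis uses 50
  max_iter: 500
  tol: 1.0e-5
  spatial: true

connectivity:
  frac: 0.05

graph:
  alpha: 0.05
  n_null: 100
  t_samples: 170

communities:
  k: auto
  restarts: 50

stats:
  alpha: 0.05
  q: 0.05
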