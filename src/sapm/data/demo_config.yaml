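# Demo pipeline configuration: a small synthetic study on the bundled
# 5-region demo network.  Sizes are deliberately small so the complete
# chain (simulate -> cluster -> search -> fit -> null -> features ->
# stats -> pupil) runs in seconds.
name: demo
seed: 0
network: demo_small
paradigm:
  TR: 2.0
  run_duration: 270
simulate:
  n_participants: {FM: 3, HC: 3}
  n_runs: 2
  noise_sd: 0.2
cluster:
  k: 5
  voxels_per_subregion: 6
  within_sd: 0.1
search:
  n_starts: 2
  n_restarts: 1
fit:
  n_restarts: 2
"null":
  reps: 40
  n_restarts: 1
pupil:
  n_trials: {FM: 6, HC: 6}
  baselines: {FM: 1920.0, HC: 1540.0}
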