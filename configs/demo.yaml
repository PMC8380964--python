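seed: 42
out_dir: results/pipeline_demo
simulate:
  n_patients: 20
  n_controls: 20
  n_volumes: 100
  n_high_motion_patients: 3
compare:
  n_perm: 500
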