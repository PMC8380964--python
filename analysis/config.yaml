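# Shared configuration for the numbered analysis drivers.
seed: 2021
out_dir: results/analysis
simulate:
  n_patients: 43          # 43 recruited, 3 planted high-motion -> 40 analysed
  n_controls: 37
  n_volumes: 100
  n_high_motion_patients: 3
compare:
  n_perm: 1000
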