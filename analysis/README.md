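Numbered drivers reproducing the study analyses on a synthetic cohort.
Run them in order from the repository root:

    python analysis/01_simulate_cohort.py
    ...
    python analysis/07_classification.py

All outputs land under `results/analysis/`; `analysis/config.yaml`
holds every parameter. `08_validation_experiments.py` reruns the
calibration checks (FWE rate, covariate contract, correlation and
classifier recovery) at reduced size.
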