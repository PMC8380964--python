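#!/usr/bin/env python
"""Calibration checks at reduced size: FWE false-cluster rate on null
cohorts, the motion-confound covariate contract, phenotype-correlation
recovery, and classifier chance level.

`scripts/acceptance.py` runs the full-size versions.
"""
from pathlib import Path

import pandas as pd

from nethom import experiments as ex

rows = [
    ("nh_oracle_max_abs_diff", ex.nh_oracle_max_abs_diff(20, 60, 0), 20),
    ("analytic_nh_limit_abs_error", ex.analytic_nh_limit_error(0.4, 2000, 0), 2000),
    ("fwe_null_cluster_rate", ex.fwe_null_cluster_rate(30, 200, 0), 30),
    ("fd_confound_rate_cov_off",
     ex.fwe_null_cluster_rate(30, 200, 1, use_covariates=False, fd_confound=True), 30),
    ("fd_confound_rate_cov_on",
     ex.fwe_null_cluster_rate(30, 200, 1, use_covariates=True, fd_confound=True), 30),
    ("planted_r05_mean_estimate", ex.correlation_recovery(0.5, 50, 2), 50),
    ("svm_null_mean_accuracy_pct", ex.svm_null_mean_accuracy(10, 3), 10),
]
tab = pd.DataFrame(rows, columns=["quantity", "value", "n"])
out = Path("results/analysis/validation.tsv")
out.parent.mkdir(parents=True, exist_ok=True)
tab.to_csv(out, sep="\t", index=False, float_format="%.6g")
print(tab.to_string(index=False))
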