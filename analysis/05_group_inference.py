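#!/usr/bin/env python
"""Voxel-wise patients-vs-controls comparison of NH with age and mean
FD as covariates; permutation max-extent FWE at the cluster level."""
from pathlib import Path

import pandas as pd

from nethom.config import load_config
from nethom.pipeline import stage_compare

cfg = load_config(Path(__file__).with_name("config.yaml"))
stage_compare(cfg)
tab = pd.read_csv(Path(cfg.out_dir) / "compare" / "clusters.tsv", sep="\t")
print(tab.to_string(index=False))
if len(tab):
    pos = (tab["direction"] == "patients>controls").sum()
    neg = (tab["direction"] == "patients<controls").sum()
    print(f"\ndissociation pattern: {pos} region(s) with increased NH, "
          f"{neg} with decreased NH in patients.")
else:
    print("\nno significant clusters.")
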