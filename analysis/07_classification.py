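#!/usr/bin/env python
"""Leave-one-out RBF-SVM classification of patients vs controls from
each significant region's mean NH."""
from pathlib import Path

import pandas as pd

from nethom.config import load_config
from nethom.pipeline import stage_classify

cfg = load_config(Path(__file__).with_name("config.yaml"))
stage_classify(cfg)
tab = pd.read_csv(Path(cfg.out_dir) / "classify" / "classification.tsv", sep="\t")
print(tab.to_string(index=False))
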