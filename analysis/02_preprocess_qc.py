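#!/usr/bin/env python
"""Temporal preprocessing and motion QC.

Drops 10 equilibration volumes, regresses the 6 motion parameters,
band-passes 0.01-0.08 Hz, and excludes subjects breaking the
2 mm / 2 deg / mean-FD 0.5 mm rule.
"""
from pathlib import Path

import pandas as pd

from nethom.config import load_config
from nethom.pipeline import stage_preprocess

cfg = load_config(Path(__file__).with_name("config.yaml"))
stage_preprocess(cfg)
qc = pd.read_csv(Path(cfg.out_dir) / "preproc" / "qc.tsv", sep="\t")
n_out = int((~qc["included"]).sum())
print(qc.to_string(index=False))
print(f"\n{len(qc) - n_out}/{len(qc)} subjects retained; {n_out} excluded "
      "for excessive head movement.")
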