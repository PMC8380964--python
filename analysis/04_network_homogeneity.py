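#!/usr/bin/env python
"""Per-subject network homogeneity maps within the derived mask
(6 mm smoothed), the measured quantity for all group statistics."""
from pathlib import Path

from nethom.config import load_config
from nethom.pipeline import stage_nh

cfg = load_config(Path(__file__).with_name("config.yaml"))
outputs = stage_nh(cfg)
print(f"wrote {len(outputs)} NH maps under {cfg.out_dir}/nh/")
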