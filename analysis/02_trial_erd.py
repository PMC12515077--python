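#!/usr/bin/env python
"""Trial-level EEG analysis: epoching, 100 uV rejection, Morlet power and
the alpha (8-13.5 Hz) ERD statistic, summarized per condition/channel."""

import pandas as pd

from common import default_config
from mubold.pipeline import run_pipeline

cfg = default_config()
out = run_pipeline(cfg, until="erd")

means = pd.read_csv(out / "erd_group_means.tsv", sep="\t")
table = means.pivot(index="condition", columns="channel", values="erd_percent")
print("Group-mean single-trial alpha ERD (%) by condition and channel:")
print(table.round(2).to_string())
print("\nContralateral organization: right-hand tasks suppress C3 (left "
      "hemisphere), left-hand tasks suppress C4; ipsilateral suppression "
      "is weaker. Planted values:", cfg.erd_percent)
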