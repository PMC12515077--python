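#!/usr/bin/env python
"""Conventional block-design fMRI analysis: HRF-convolved condition
boxcars in a fixed-effects GLM, hand-lateralized contrasts, and the
per-subject precision screen against the contralateral sensorimotor ROI."""

import pandas as pd

from common import default_config
from mubold.pipeline import run_pipeline

cfg = default_config()
out = run_pipeline(cfg, until="overlap")  # the screen is computed with overlap

print("Block-design fixed-effects contrasts (p < %.3g, k = %d):"
      % (cfg.p_voxel, cfg.extent_k))
for pretty in ("ME_RH>ME_LH", "ME_LH>ME_RH", "MI_RH>MI_LH", "MI_LH>MI_RH"):
    safe = pretty.replace(">", "gt")
    table = pd.read_csv(out / f"block_{safe}_clusters.tsv", sep="\t")
    peak = f", peak t = {table.peak_t.iloc[0]:.2f}" if len(table) else ""
    print(f"  {pretty}: {len(table)} cluster(s){peak}")

screen = pd.read_csv(out / "subject_screen.tsv", sep="\t")
kept = screen.kept.sum()
print(f"\nPrecision screen (> {cfg.precision_screen_percent:g} % mean "
      f"precision of the two imagery contrasts against the contralateral "
      f"sensorimotor ROI): kept {kept}/{len(screen)} subjects")
print(screen[["subject", "mean_precision_percent", "kept"]]
      .to_string(index=False))
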