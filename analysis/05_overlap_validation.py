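#!/usr/bin/env python
"""Validation of the EEG-informed maps against the block-design maps:
Dice / precision / recall over the binarized images, whole volume and
restricted to the contralateral sensorimotor (planted) region."""

import pandas as pd

from common import default_config
from mubold.metrics import dice_from_precision_recall
from mubold.pipeline import run_pipeline

cfg = default_config()
out = run_pipeline(cfg, until="overlap")

rep = pd.read_csv(out / "overlap_report.tsv", sep="\t")
cols = ["eeg_contrast", "block_contrast", "dice", "precision", "recall"]
print("Whole-volume overlap of EEG-informed vs block-design maps:")
print(rep[cols].round(3).to_string(index=False))
print("\nRestricted to the contralateral sensorimotor region:")
roi_cols = ["eeg_contrast", "roi_dice", "roi_precision", "roi_recall"]
print(rep[roi_cols].round(3).to_string(index=False))

ok = True
for _, row in rep.iterrows():
    tp, fp, fn = int(row.TP), int(row.FP), int(row.FN)
    if tp + fp == 0 or tp + fn == 0:
        continue  # precision or recall undefined
    p, r = tp / (tp + fp), tp / (tp + fn)
    if p + r > 0:
        dice = 2 * tp / (2 * tp + fp + fn)
        ok &= abs(dice_from_precision_recall(p, r) - dice) < 1e-12
print(f"\nDice = harmonic mean of precision and recall on every row: {ok}")
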