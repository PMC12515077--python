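"""Reference values reported by the original motor EEG-fMRI study.

These are inputs to internal-consistency checks (e.g. the Dice /
precision / recall identity on the published overlap triples) and targets
for the synthetic validation; they are not produced by this package.
"""

#: Published overlap of the EEG-informed maps against the block-design
#: maps, whole volume: (dice, precision, recall) as fractions.
REPORTED_OVERLAP = {
    "ME_right_hand": {"dice": 0.25, "precision": 0.93, "recall": 0.14},
    "ME_left_hand": {"dice": 0.30, "precision": 0.60, "recall": 0.20},
    "MI_right_hand": {"dice": 0.04, "precision": 0.14, "recall": 0.02},
}

#: Same metrics restricted to the contralateral sensorimotor region.
REPORTED_OVERLAP_ROI = {
    "ME_right_hand": {"dice": 0.42, "precision": 1.00, "recall": 0.26},
    "ME_left_hand": {"dice": 0.52, "precision": 0.92, "recall": 0.36},
    "MI_right_hand": {"dice": 0.06, "precision": 0.95, "recall": 0.03},
}

#: Group-mean contralateral alpha ERD during hand motor imagery (percent).
REPORTED_MI_ERD_PERCENT = {"MI_RH": -16.18, "MI_LH": -18.58}

#: Group-level ERD vs ROI-mean-t regression (n = 17).
REPORTED_ERD_BOLD_R = -0.49

#: Timing of the paradigm (seconds).
REPORTED_TASK_BLOCK_S = 22.0
REPORTED_REST_BLOCK_S = 16.0
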