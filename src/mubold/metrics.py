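"""Map-overlap validation metrics, precision-based subject selection and
framewise-displacement motion QC.

Overlap between an evaluated binary map A (here: the EEG-informed result)
and a reference map B (the block-design fMRI result) is summarized by

    dice      = 2 TP / (2 TP + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

with TP = |A and B|, FP = |A minus B|, FN = |B minus A|.  Undefined ratios
(empty denominators) are reported as None, never as 0, so aggregation
cannot silently bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MotionParams

PRECISION_SCREEN_PERCENT = 15.0
FD_SPHERE_RADIUS_MM = 50.0


@dataclass
class OverlapReport:
    TP: int
    FP: int
    FN: int

    @property
    def dice(self) -> float | None:
        den = 2 * self.TP + self.FP + self.FN
        return 2.0 * self.TP / den if den else None

    @property
    def precision(self) -> float | None:
        den = self.TP + self.FP
        return self.TP / den if den else None

    @property
    def recall(self) -> float | None:
        den = self.TP + self.FN
        return self.TP / den if den else None

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        return {
            "TP": self.TP, "FP": self.FP, "FN": self.FN,
            "dice": None if self.dice is None else scale * self.dice,
            "precision": None if self.precision is None else scale * self.precision,
            "recall": None if self.recall is None else scale * self.recall,
        }


def dice_from_precision_recall(precision: float, recall: float) -> float | None:
    """Dice as the harmonic mean of precision and recall; None if both 0."""
    if precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def overlap(A: np.ndarray, B: np.ndarray, roi: np.ndarray | None = None) -> OverlapReport:
    """Voxel-count overlap of evaluated map A against reference map B,
    optionally after intersecting both with a region-of-interest mask."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError("maps must share a grid")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != A.shape:
            raise ValueError("roi must share the maps' grid")
        A = A & roi
        B = B & roi
    tp = int(np.sum(A & B))
    fp = int(np.sum(A & ~B))
    fn = int(np.sum(B & ~A))
    return OverlapReport(tp, fp, fn)


def subject_precision_screen(
    subject_maps: dict[object, dict[str, np.ndarray]],
    roi_by_contrast: dict[str, np.ndarray],
    threshold_percent: float = PRECISION_SCREEN_PERCENT,
) -> tuple[list, pd.DataFrame]:
    """Retain subjects whose mean precision over the two hand-lateralized
    MI contrast maps, against the corresponding contralateral sensorimotor
    ROI, is strictly greater than the threshold (default 15 %).

    ``subject_maps[subject][contrast]`` are voxel-thresholded binary maps;
    ``roi_by_contrast`` names the same contrasts.  Subjects whose maps are
    empty get undefined precision, treated as 0 for the screen.
    """
    contrasts = list(roi_by_contrast)
    rows = []
    kept = []
    for subject, maps in subject_maps.items():
        precisions = []
        for con in contrasts:
            if con not in maps:
                raise KeyError(f"subject {subject!r} is missing contrast {con!r}")
            rep = overlap(maps[con], roi_by_contrast[con])
            # against an ROI reference, TP+FP = |map|; empty map -> undefined
            p = rep.precision
            precisions.append(0.0 if p is None else p)
        mean_pct = 100.0 * float(np.mean(precisions))
        keep = mean_pct > threshold_percent
        if keep:
            kept.append(subject)
        rows.append({"subject": subject, "mean_precision_percent": mean_pct,
                     "kept": keep,
                     **{f"precision_{c}": 100.0 * p for c, p in zip(contrasts, precisions)}})
    return kept, pd.DataFrame(rows)


@dataclass
class MotionSummary:
    fd_mm: np.ndarray
    mean_fd_mm: float
    excluded: bool = False


def framewise_displacement(motion: MotionParams,
                           sphere_radius_mm: float = FD_SPHERE_RADIUS_MM) -> MotionSummary:
    """Power-convention framewise displacement: per volume the sum of
    absolute backward differences of the 3 translations (mm) plus the 3
    rotations converted to arc length on a 50 mm sphere; the first volume
    is 0 by convention."""
    p = motion.params
    if p.shape[0] < 2:
        raise ValueError("need at least 2 volumes for FD")
    d = np.abs(np.diff(p, axis=0))
    fd = d[:, :3].sum(axis=1) + sphere_radius_mm * d[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd])
    return MotionSummary(fd_mm=fd, mean_fd_mm=float(fd.mean()))


def flag_high_motion(summaries: list[MotionSummary], n_sd: float = 3.0) -> list[MotionSummary]:
    """Flag subjects whose mean FD exceeds the group mean by more than
    n_sd group standard deviations (the exclusion rule is an
    interpretation of 'FD higher than three times the group SD')."""
    means = np.array([s.mean_fd_mm for s in summaries])
    mu, sd = means.mean(), means.std()
    out = []
    for s in summaries:
        out.append(MotionSummary(s.fd_mm, s.mean_fd_mm,
                                 excluded=bool(s.mean_fd_mm > mu + n_sd * sd)))
    return out
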