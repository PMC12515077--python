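"""Cross-modal coupling: contralateral high-alpha ERD vs. ROI-mean BOLD t.

For each subject and hand-imagery task, the contralateral electrode's
high-alpha (10.5-13.5 Hz) trial ERD is paired with the mean first-level
t statistic inside the contralateral sensorimotor ROI (voxels passing
p < 0.001).  A linear regression over the pooled samples tests the
hypothesized negative covariation between alpha suppression and BOLD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import StatMap

#: Task -> contralateral electrode.
TASK_ELECTRODE = {"MI_RH": "C3", "MI_LH": "C4"}
HIGH_ALPHA_BAND = (10.5, 13.5)


def roi_mean_t(stat_map: StatMap, roi: np.ndarray, p_voxel: float = 0.001) -> float | None:
    """Mean t over ROI voxels that individually pass the one-sided voxel
    threshold; None (undefined) if no ROI voxel passes."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stat_map.data.shape:
        raise ValueError("ROI and map grids differ")
    thr = stats.t.isf(p_voxel, stat_map.df)
    vals = stat_map.data[roi]
    vals = vals[np.isfinite(vals) & (vals > thr)]
    if vals.size == 0:
        return None
    return float(vals.mean())


@dataclass
class CouplingSample:
    subject: object
    task: str  # MI_RH or MI_LH
    contralateral_erd: float  # percent, high-alpha band
    roi_mean_t: float

    def __post_init__(self) -> None:
        if self.task not in TASK_ELECTRODE:
            raise ValueError(f"task must be one of {sorted(TASK_ELECTRODE)}")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int

    def summary(self) -> str:
        return (f"slope={self.slope:.4f} intercept={self.intercept:.4f} "
                f"r={self.pearson_r:.3f} p={self.p_value:.4g} n={self.n}")


def erd_bold_regression(samples: list[CouplingSample] | pd.DataFrame) -> RegressionResult:
    """OLS of ROI-mean t on contralateral ERD; Pearson r with its exact
    two-sided p from the t transform (n - 2 df)."""
    if isinstance(samples, pd.DataFrame):
        x = samples["contralateral_erd"].to_numpy(dtype=float)
        y = samples["roi_mean_t"].to_numpy(dtype=float)
    else:
        x = np.array([s.contralateral_erd for s in samples], dtype=float)
        y = np.array([s.roi_mean_t for s in samples], dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            pearson_r=float(res.rvalue), p_value=float(res.pvalue),
                            n=len(x))


def samples_frame(samples: list[CouplingSample]) -> pd.DataFrame:
    return pd.DataFrame([{"subject": s.subject, "task": s.task,
                          "contralateral_erd": s.contralateral_erd,
                          "roi_mean_t": s.roi_mean_t} for s in samples])
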