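"""Mass-univariate GLM estimation, t-contrasts and cluster thresholding.

Every voxel's time series is regressed on a shared design matrix by
ordinary least squares under an i.i.d. homoscedastic error model (no
prewhitening by default; an AR(1) Cochrane-Orcutt option is available).
Directional hypotheses are tested with one-sided t-contrasts; maps are
thresholded voxelwise (p < 0.001 by default) and cleaned with a cluster
extent threshold under 18-connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import StatMap
from .regressors import (
    DEFAULT_HIGHPASS_S,
    DesignMatrix,
    HrfParams,
    PowerSeries,
    canonical_hrf,
    condition_mask,
    dct_highpass,
    make_regressor,
)

logger = logging.getLogger(__name__)


@dataclass
class GlmFit:
    """OLS estimates per voxel: betas (columns x voxels), residual variance,
    residual degrees of freedom and the design's (X'X)^-1."""

    betas: np.ndarray
    sigma2: np.ndarray
    df: int
    xtx_inv: np.ndarray
    labels: list[str]


def _as_matrix(X: DesignMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, DesignMatrix):
        return X.X, list(X.labels)
    X = np.asarray(X, dtype=float)
    return X, [f"col{j}" for j in range(X.shape[1])]


def fit_glm(Y: np.ndarray, X: DesignMatrix | np.ndarray) -> GlmFit:
    """Ordinary least squares of every voxel (column of Y) on X.

    Y is volumes x voxels; X must be full column rank with as many rows.
    """
    Xm, labels = _as_matrix(X)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, np.newaxis]
    if Y.shape[0] != Xm.shape[0]:
        raise ValueError("Y and X row counts differ")
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        raise ValueError("design matrix is rank deficient")
    df = Xm.shape[0] - rank
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    xtx = Xm.T @ Xm
    xtx_inv = np.linalg.inv(xtx)
    betas = xtx_inv @ (Xm.T @ Y)
    resid = Y - Xm @ betas
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    return GlmFit(betas, sigma2, df, xtx_inv, labels)


def ar1_prewhiten(Y: np.ndarray, X: DesignMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Cochrane-Orcutt AR(1) prewhitening: estimate the pooled lag-1
    residual autocorrelation from an OLS fit and difference both sides.
    Returns (Y*, X*, phi_hat); row 1..n-1 transforms, first row dropped."""
    Xm, _ = _as_matrix(X)
    fit = fit_glm(Y, Xm)
    resid = np.asarray(Y, dtype=float) - Xm @ fit.betas
    num = np.sum(resid[1:] * resid[:-1])
    den = np.sum(resid[:-1] ** 2)
    phi = float(num / den) if den > 0 else 0.0
    phi = float(np.clip(phi, -0.99, 0.99))
    Yw = Y[1:] - phi * Y[:-1]
    Xw = Xm[1:] - phi * Xm[:-1]
    return Yw, Xw, phi


def contrast_vector(labels: list[str], weights: dict[str, float]) -> np.ndarray:
    """Build a contrast vector from label -> weight; unlisted labels get 0."""
    missing = set(weights) - set(labels)
    if missing:
        raise KeyError(f"contrast names unknown columns: {sorted(missing)}")
    c = np.array([weights.get(lab, 0.0) for lab in labels])
    if not np.any(c):
        raise ValueError("contrast vector is all zero")
    return c


#: The four lateralized EEG-informed contrasts.  "C3 < C4 - ME" asks where
#: BOLD covaries more negatively with C3 alpha power than with C4 alpha
#: power during motor execution: +1 on C4-ME, -1 on C3-ME.
EEG_CONTRASTS = {
    "C3<C4-ME": {"C4-ME": 1.0, "C3-ME": -1.0},
    "C4<C3-ME": {"C3-ME": 1.0, "C4-ME": -1.0},
    "C3<C4-MI": {"C4-MI": 1.0, "C3-MI": -1.0},
    "C4<C3-MI": {"C3-MI": 1.0, "C4-MI": -1.0},
}

#: Block (unimodal) contrasts between hands within a mode.
BLOCK_CONTRASTS = {
    "ME_RH>ME_LH": {"ME_RH": 1.0, "ME_LH": -1.0},
    "ME_LH>ME_RH": {"ME_LH": 1.0, "ME_RH": -1.0},
    "MI_RH>MI_LH": {"MI_RH": 1.0, "MI_LH": -1.0},
    "MI_LH>MI_RH": {"MI_LH": 1.0, "MI_RH": -1.0},
}


def t_contrast(fit: GlmFit, c: np.ndarray | dict[str, float]) -> np.ndarray:
    """Voxelwise t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c).

    Voxels with a zero denominator come back NaN (logged), never inf.
    """
    if isinstance(c, dict):
        c = contrast_vector(fit.labels, c)
    c = np.asarray(c, dtype=float)
    if c.shape[0] != fit.betas.shape[0]:
        raise ValueError("contrast length does not match design columns")
    eff = c @ fit.betas
    var_unit = float(c @ fit.xtx_inv @ c)
    var = fit.sigma2 * var_unit
    t = np.full_like(eff, np.nan)
    # a voxel fitted (numerically) perfectly has no error estimate
    scale = np.max(fit.sigma2) if fit.sigma2.size else 0.0
    ok = var > max(scale, 1.0) * var_unit * 1e-24
    t[ok] = eff[ok] / np.sqrt(var[ok])
    n_bad = int(np.sum(~ok))
    if n_bad:
        logger.info("t_contrast: %d voxels with zero error variance set invalid", n_bad)
    return t


def block_condition_columns(
    paradigm,
    n_volumes: int | None = None,
    tr_s: float = 2.0,
    hrf_params: HrfParams = HrfParams(),
    highpass_cutoff_s: float | None = DEFAULT_HIGHPASS_S,
    micro_dt_s: float = 0.1,
    run: int = 0,
) -> dict[str, np.ndarray]:
    """One HRF-convolved, TR-sampled, high-passed boxcar column per task
    condition, built on a fine time grid through the same resampling path
    as the EEG-informed regressors."""
    from .core import TASK_CONDITIONS  # local to avoid cycle at import time

    fs = 1.0 / micro_dt_s
    if n_volumes is None:
        n_volumes = int(round(paradigm.runs[run].run_length_s / tr_s))
    n = int(round(paradigm.runs[run].run_length_s * fs))
    hrf = canonical_hrf(micro_dt_s, hrf_params)
    cols = {}
    for cond in TASK_CONDITIONS:
        box = np.zeros(n)
        for b in paradigm.condition_blocks(cond, run):
            box[int(np.floor(b.onset * fs)):int(np.floor(b.end * fs))] = 1.0
        series = PowerSeries(cond, fs, box)
        cols[cond] = make_regressor(series, hrf, n_volumes, tr_s, highpass_cutoff_s)
    return cols


def block_design(
    paradigm,
    motion,
    tr_s: float = 2.0,
    hrf_params: HrfParams = HrfParams(),
    highpass_cutoff_s: float | None = DEFAULT_HIGHPASS_S,
    micro_dt_s: float = 0.1,
    run: int = 0,
) -> DesignMatrix:
    """Conventional block design for one scan: condition boxcars plus
    motion parameters and an intercept."""
    from .core import TASK_CONDITIONS
    from .regressors import assemble_design

    cols = block_condition_columns(paradigm, None, tr_s, hrf_params,
                                   highpass_cutoff_s, micro_dt_s, run)
    return assemble_design([cols], [motion], shared_labels=tuple(TASK_CONDITIONS))


def second_level(
    contrast_maps: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> StatMap:
    """Random-effects group model: per-voxel OLS of subject contrast values
    on an intercept plus mean-centered covariates; the returned map is the
    intercept's t (the group mean effect).

    ``contrast_maps`` is subjects x voxels (flattened) or a list of equally
    shaped arrays.  Categorical covariates (e.g. sex, handedness) must be
    numerically coded.
    """
    maps = np.asarray([np.ravel(m) for m in contrast_maps], dtype=float)
    n_sub = maps.shape[0]
    if covariates is not None and len(covariates):
        C = np.asarray(covariates, dtype=float)
        C = C - C.mean(axis=0)
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("degenerate covariates (collinear after centering)")
        X = np.column_stack([np.ones(n_sub), C])
    else:
        X = np.ones((n_sub, 1))
    if n_sub < X.shape[1] + 3:
        raise ValueError("need at least 3 more subjects than covariates")
    fit = fit_glm(maps, X)
    c = np.zeros(X.shape[1])
    c[0] = 1.0
    t = t_contrast(fit, c)
    return StatMap(t, df=fit.df)


CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def threshold_and_cluster(
    stat_map: StatMap,
    p_voxel: float = 0.001,
    extent_k: int = 10,
    connectivity: int = 18,
) -> tuple[np.ndarray, pd.DataFrame]:
    """One-sided voxel threshold then cluster extent filtering.

    A voxel survives iff its one-sided p-value (upper tail of t with the
    map's df) is < p_voxel; connected components (18-connectivity by
    default) smaller than extent_k voxels are removed.  Returns the binary
    map and a cluster table sorted by peak t, with peak voxel indices and
    mm coordinates when an affine is present.
    """
    t_thr = stats.t.isf(p_voxel, stat_map.df)
    data = stat_map.data
    binary = np.zeros(data.shape, dtype=bool)
    finite = np.isfinite(data)
    binary[finite] = data[finite] > t_thr
    if binary.ndim != 3:
        raise ValueError("cluster extraction requires a 3D map")
    lab, n_lab = ndimage.label(binary, structure=CONNECTIVITY_STRUCTS[connectivity])
    rows = []
    out = np.zeros_like(binary)
    for i in range(1, n_lab + 1):
        mask = lab == i
        size = int(mask.sum())
        if size < extent_k:
            continue
        out |= mask
        masked = np.where(mask, data, -np.inf)
        peak = np.unravel_index(np.argmax(masked), data.shape)
        row = {"size": size, "peak_t": float(data[peak]),
               "peak_i": peak[0], "peak_j": peak[1], "peak_k": peak[2]}
        if stat_map.affine is not None:
            mm = stat_map.affine @ np.array([*peak, 1.0])
            row.update({"peak_x_mm": mm[0], "peak_y_mm": mm[1], "peak_z_mm": mm[2]})
        rows.append(row)
    columns = ["size", "peak_t", "peak_i", "peak_j", "peak_k"]
    if stat_map.affine is not None:
        columns += ["peak_x_mm", "peak_y_mm", "peak_z_mm"]
    table = pd.DataFrame(rows, columns=columns)
    if len(table):
        table = table.sort_values("peak_t", ascending=False).reset_index(drop=True)
    return out, table


def highpass_bold(Y: np.ndarray, tr_s: float, cutoff_s: float = DEFAULT_HIGHPASS_S) -> np.ndarray:
    """Apply the same DCT high-pass used for the regressors to the data
    (volumes x voxels), as SPM-style analyses filter both sides."""
    return dct_highpass(np.asarray(Y, dtype=float), tr_s, cutoff_s)
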