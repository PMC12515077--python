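"""EEG-informed fMRI regressor construction.

The continuous alpha-band power of C3 and C4 is masked by condition
(square waves over the ME, MI and REST block periods), convolved with the
canonical double-gamma hemodynamic response function, resampled to the
scanner rate (TR = 2 s, i.e. 0.5 Hz), high-pass filtered with a 128 s
cut-off (discrete-cosine residualization) and mean-centered, yielding six
regressors per scan: C3-ME, C3-MI, C3-REST, C4-ME, C4-MI, C4-REST.
Motion parameters and a per-scan intercept complete the design matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import gamma

from .core import REST, EEGRecording, MotionParams, Paradigm
from .eeg_features import ALPHA_BAND, DEFAULT_N_CYCLES, TrialSet, morlet_tfr

logger = logging.getLogger(__name__)

EEG_REGRESSOR_LABELS = ("C3-ME", "C3-MI", "C3-REST", "C4-ME", "C4-MI", "C4-REST")
DEFAULT_HIGHPASS_S = 128.0


@dataclass(frozen=True)
class HrfParams:
    """Canonical (SPM-convention) double-gamma HRF parameters, seconds."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_to_undershoot_ratio: float = 6.0
    kernel_length_s: float = 32.0


@dataclass
class PowerSeries:
    """Band-averaged alpha power (uV^2) of one electrode over a run."""

    electrode: str
    sampling_rate_hz: float
    values: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.values)


def canonical_hrf(dt_s: float, params: HrfParams = HrfParams()) -> np.ndarray:
    """Canonical HRF kernel sampled on [0, kernel_length] at dt, peak
    normalized to 1: h(t) = g(t; 6, 1) - g(t; 16, 1)/6."""
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, params.kernel_length_s + dt_s / 2, dt_s)
    h = (gamma.pdf(t, params.peak_delay_s / params.peak_dispersion_s,
                   scale=params.peak_dispersion_s)
         - gamma.pdf(t, params.undershoot_delay_s / params.undershoot_dispersion_s,
                     scale=params.undershoot_dispersion_s)
         / params.peak_to_undershoot_ratio)
    return h / h.max()


def continuous_band_power(
    rec: EEGRecording,
    electrodes: tuple[str, ...] = ("C3", "C4"),
    band_hz: tuple[float, float] = ALPHA_BAND,
    freq_step_hz: float = 0.5,
    n_cycles: float = DEFAULT_N_CYCLES,
) -> dict[str, PowerSeries]:
    """Continuous Morlet band power per electrode (same estimator as the
    trial analysis), averaged over the band's frequency bins; edge samples
    inside the wavelet support are filled with the nearest valid value."""
    freqs = np.arange(band_hz[0], band_hz[1] + 1e-9, freq_step_hz)
    out = {}
    for e in electrodes:
        sig = rec.channel(e)  # raises KeyError if missing
        tfr = morlet_tfr(sig[np.newaxis], rec.sampling_rate_hz, freqs, n_cycles)
        power = tfr.power[0]  # freqs x times
        n = power.shape[1]
        series = np.empty(n)
        # unweighted mean over band bins, then nearest-valid edge fill;
        # all band bins share (up to one sample) the same invalid margin
        band_mean = power.mean(axis=0)
        valid_any = tfr.valid.all(axis=0)
        if valid_any.any():
            idx = np.arange(n)
            first, last = idx[valid_any][0], idx[valid_any][-1]
            series[:] = band_mean
            series[:first] = band_mean[first]
            series[last + 1:] = band_mean[last]
        else:
            series[:] = band_mean
        out[e] = PowerSeries(e, rec.sampling_rate_hz, series, rec.t0_s)
    return out


def impute_bad_trials(series: PowerSeries, trials: TrialSet,
                      paradigm: Paradigm, run: int = 0) -> PowerSeries:
    """Replace each bad trial's span in the continuous power series by the
    pointwise mean of same-condition good trials' spans (aligned to onset).

    A condition with no good trials leaves its bad spans unchanged (logged).
    """
    fs = series.sampling_rate_hz
    values = series.values.copy()
    n_span = int(round(trials.trials[0].duration_s * fs)) if trials.trials else 0
    by_cond: dict[str, list[np.ndarray]] = {}
    for t in trials.trials:
        if t.good:
            i0 = int(np.floor((t.onset_s - series.t0_s) * fs))
            seg = series.values[i0:i0 + n_span]
            if len(seg) == n_span:
                by_cond.setdefault(t.condition, []).append(seg)
    for t in trials.trials:
        if t.good:
            continue
        good_segs = by_cond.get(t.condition)
        if not good_segs:
            logger.warning("no good %s trials to impute from; span left unchanged",
                           t.condition)
            continue
        i0 = int(np.floor((t.onset_s - series.t0_s) * fs))
        values[i0:i0 + n_span] = np.mean(good_segs, axis=0)
    return PowerSeries(series.electrode, fs, values, series.t0_s)


def _sample_condition_labels(paradigm: Paradigm, n: int, fs: float,
                             run: int = 0) -> np.ndarray:
    """Per-sample condition group label ('ME' | 'MI' | 'REST'); rest is the
    default so the three groups always partition the run exactly."""
    labels = np.full(n, REST, dtype=object)
    for group in ("ME", "MI"):
        for b in paradigm.condition_blocks(group, run):
            i0 = int(np.floor(b.onset * fs))
            i1 = int(np.floor(b.end * fs))
            labels[i0:min(i1, n)] = group
    return labels


def condition_mask(series: PowerSeries, paradigm: Paradigm, condition: str,
                   run: int = 0) -> PowerSeries:
    """Zero the power series outside the condition's block intervals.

    'ME' and 'MI' masks are the union over both hands' blocks; 'REST'
    covers rest blocks (including trailing pad).  The three masked series
    sum to the original series at every sample.
    """
    labels = _sample_condition_labels(paradigm, series.n_samples,
                                      series.sampling_rate_hz, run)
    values = np.where(labels == condition, series.values, 0.0)
    return PowerSeries(series.electrode, series.sampling_rate_hz, values,
                       series.t0_s)


def dct_highpass_basis(n: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """SPM-style discrete-cosine drift basis: columns k = 0..K with
    K = floor(2 * n * TR / cutoff), i.e. all components of period > cutoff
    plus the constant."""
    K = int(np.floor(2.0 * n * tr_s / cutoff_s))
    i = np.arange(n)
    cols = [np.ones(n) / np.sqrt(n)]
    for k in range(1, K + 1):
        cols.append(np.sqrt(2.0 / n) * np.cos(np.pi * k * (2 * i + 1) / (2.0 * n)))
    return np.column_stack(cols)


def dct_highpass(x: np.ndarray, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Residualize columns (or a vector) against the DCT drift basis —
    removes fluctuations slower than the cutoff and the mean."""
    C = dct_highpass_basis(x.shape[0], tr_s, cutoff_s)
    x2d = x[:, np.newaxis] if x.ndim == 1 else x
    resid = x2d - C @ (C.T @ x2d)  # C is orthonormal
    return resid[:, 0] if x.ndim == 1 else resid


def make_regressor(
    masked: PowerSeries,
    hrf: np.ndarray,
    n_volumes: int,
    tr_s: float = 2.0,
    highpass_cutoff_s: float | None = DEFAULT_HIGHPASS_S,
    downsample: str = "block_average",
    center: bool = True,
) -> np.ndarray:
    """Condition-masked power -> design-matrix column at the scanner rate.

    Causal convolution with the HRF kernel (sampled at the series rate),
    within-TR block averaging down to one value per volume (anti-aliasing;
    ``downsample='point'`` takes the sample at each volume onset instead),
    then DCT high-pass filtering and mean-centering.
    """
    fs = masked.sampling_rate_hz
    per_tr = tr_s * fs
    if masked.n_samples + 0.5 < n_volumes * per_tr:
        raise ValueError("power series shorter than the scan")
    conv = fftconvolve(masked.values, hrf)[: masked.n_samples] / fs
    col = np.empty(n_volumes)
    for v in range(n_volumes):
        i0 = int(np.floor(v * per_tr))
        i1 = int(np.floor((v + 1) * per_tr))
        col[v] = conv[i0] if downsample == "point" else conv[i0:max(i1, i0 + 1)].mean()
    if highpass_cutoff_s is not None:
        col = dct_highpass(col, tr_s, highpass_cutoff_s)
    if center:
        col = col - col.mean()
    return col


def build_regressor_set(
    power: dict[str, PowerSeries],
    paradigm: Paradigm,
    n_volumes: int,
    tr_s: float = 2.0,
    hrf_params: HrfParams = HrfParams(),
    highpass_cutoff_s: float | None = DEFAULT_HIGHPASS_S,
    run: int = 0,
) -> dict[str, np.ndarray]:
    """The six EEG-informed columns (electrode x condition) for one scan."""
    hrf = canonical_hrf(1.0 / next(iter(power.values())).sampling_rate_hz)
    out = {}
    for e in ("C3", "C4"):
        for cond in ("ME", "MI", "REST"):
            masked = condition_mask(power[e], paradigm, cond, run)
            out[f"{e}-{cond}"] = make_regressor(masked, hrf, n_volumes, tr_s,
                                                highpass_cutoff_s)
    return out


@dataclass
class DesignMatrix:
    """Design matrix with labeled columns and per-scan row ranges."""

    X: np.ndarray
    labels: list[str]
    scan_slices: list[slice] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.X[:, self.labels.index(label)]


def _collinear_columns(X: np.ndarray, labels: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [labels[i] for i in np.where(diag < tol)[0]]


def assemble_design(
    regressor_sets: list[dict[str, np.ndarray]],
    motion: list[MotionParams],
    shared_labels: tuple[str, ...] = EEG_REGRESSOR_LABELS,
) -> DesignMatrix:
    """Concatenate scans into one fixed-effects design.

    Shared (EEG) regressors occupy common labeled columns filled per scan
    row block; motion parameters and the intercept are block-diagonal per
    scan.  Raises on rank deficiency, naming the collinear columns.
    """
    if len(regressor_sets) != len(motion):
        raise ValueError("one MotionParams per scan required")
    n_scans = len(regressor_sets)
    rows_per = []
    for rs, m in zip(regressor_sets, motion):
        lens = {len(col) for col in rs.values()} | {m.n_volumes}
        if len(lens) != 1:
            raise ValueError("regressor and motion lengths differ within a scan")
        rows_per.append(lens.pop())
    total = sum(rows_per)
    labels = list(shared_labels)
    labels += [f"motion{j + 1}_scan{s}" for s in range(n_scans) for j in range(6)]
    labels += [f"intercept_scan{s}" for s in range(n_scans)]
    X = np.zeros((total, len(labels)))
    scan_slices = []
    r0 = 0
    for s, (rs, m) in enumerate(zip(regressor_sets, motion)):
        sl = slice(r0, r0 + rows_per[s])
        scan_slices.append(sl)
        for j, lab in enumerate(shared_labels):
            X[sl, j] = rs[lab]
        mcol = len(shared_labels) + 6 * s
        X[sl, mcol:mcol + 6] = m.params
        X[sl, len(shared_labels) + 6 * n_scans + s] = 1.0
        r0 += rows_per[s]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, labels)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(X, labels, scan_slices)
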