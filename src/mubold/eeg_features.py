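"""EEG trial epoching, artifact rejection, Morlet time-frequency power and
the event-related desynchronization (ERD) statistic.

ERD is the percentage change of band power relative to a pre-trial
baseline:

    ERD(t, f, c) = (P(t, f, c) - R(f, c)) / R(f, c) * 100 %

where P is Morlet wavelet power and R the mean power in the 1.0-0.1 s
window before trial onset.  The single-trial alpha ERD averages ERD over
the alpha band (8-13.5 Hz) from 0.5 s after trial onset to trial end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from mne.time_frequency import tfr_array_morlet
from scipy.signal import butter, sosfiltfilt

from .core import EEGRecording, Paradigm

#: Analysis frequency axis: 1-40 Hz in 0.5 Hz steps.
DEFAULT_FREQS = np.arange(1.0, 40.0 + 1e-9, 0.5)
DEFAULT_N_CYCLES = 7
ALPHA_BAND = (8.0, 13.5)
HIGH_ALPHA_BAND = (10.5, 13.5)

#: Epoch window relative to the trial: 2 s before onset to 1 s after offset.
EPOCH_PRE_S = 2.0
EPOCH_POST_S = 1.0
#: Baseline window relative to trial onset.
BASELINE_WINDOW_S = (-1.0, -0.1)
#: ERD averaging window starts this long after trial onset.
ERD_WINDOW_START_S = 0.5

SD_REJECT_THRESHOLD_UV = 100.0


def bandpass_filter(rec: EEGRecording, low_hz: float, high_hz: float,
                    order: int = 4) -> EEGRecording:
    """Zero-phase (forward-backward) Butterworth bandpass."""
    nyq = rec.sampling_rate_hz / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < "
                         f"Nyquist ({nyq} Hz)")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.sampling_rate_hz,
                 output="sos")
    filtered = sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(list(rec.channel_names), rec.sampling_rate_hz, filtered,
                        rec.t0_s)


@dataclass
class TrialEpoch:
    """One trial's epoch: channels x samples in [onset-2 s, offset+1 s)."""

    condition: str
    onset_s: float
    duration_s: float
    start_sample: int
    data: np.ndarray
    good: bool = True


@dataclass
class TrialSet:
    """Epoched trials with rejection flags; all epochs have equal length."""

    trials: list[TrialEpoch]
    sampling_rate_hz: float
    pre_s: float = EPOCH_PRE_S
    post_s: float = EPOCH_POST_S

    def __len__(self) -> int:
        return len(self.trials)

    def good_trials(self) -> list[TrialEpoch]:
        return [t for t in self.trials if t.good]


def segment_trials(rec: EEGRecording, paradigm: Paradigm, run: int = 0,
                   pre_s: float = EPOCH_PRE_S, post_s: float = EPOCH_POST_S) -> TrialSet:
    """Cut one epoch per paradigm trial.

    Epoch windows are half-open [onset - pre, offset + post) in samples,
    with sample index floor(t * rate); the sample count is identical across
    trials (taken from the common trial duration).
    """
    fs = rec.sampling_rate_hz
    trials = paradigm.runs[run].trials
    epochs = []
    n_per: int | None = None
    for k, tr in enumerate(trials):
        start = int(np.floor((tr.onset - pre_s - rec.t0_s) * fs))
        n = int(round((pre_s + tr.duration + post_s) * fs))
        if n_per is None:
            n_per = n
        elif n != n_per:
            raise ValueError("trials have unequal durations; epochs would differ")
        if start < 0 or start + n > rec.n_samples:
            raise ValueError(f"epoch for trial {k} ({tr.label} at {tr.onset} s) "
                             "exceeds recording bounds")
        epochs.append(TrialEpoch(tr.label, tr.onset, tr.duration, start,
                                 rec.data[:, start:start + n].copy()))
    return TrialSet(epochs, fs, pre_s, post_s)


def reject_bad_trials(trials: TrialSet,
                      sd_threshold_uv: float = SD_REJECT_THRESHOLD_UV) -> TrialSet:
    """Flag a trial bad iff any channel's within-epoch sample standard
    deviation strictly exceeds the threshold (default 100 uV)."""
    out = []
    for t in trials.trials:
        sd = t.data.std(axis=1)
        out.append(TrialEpoch(t.condition, t.onset_s, t.duration_s, t.start_sample,
                              t.data, good=bool(not np.any(sd > sd_threshold_uv))))
    return TrialSet(out, trials.sampling_rate_hz, trials.pre_s, trials.post_s)


@dataclass
class TimeFrequencyMap:
    """Morlet power P(c, f, t) in uV^2 with an edge-validity mask.

    ``valid[f, t]`` is False where the wavelet's half support at that
    frequency extends past either data edge.
    """

    power: np.ndarray  # channels x freqs x times
    freqs: np.ndarray
    times: np.ndarray
    sampling_rate_hz: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones((len(self.freqs), len(self.times)), dtype=bool)


@dataclass
class ErdMap:
    """ERD(c, f, t) in percent, same axes/validity semantics as the TFR."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray


def wavelet_half_support_s(freq: float, n_cycles: float = DEFAULT_N_CYCLES) -> float:
    """Half length of the Morlet wavelet (5 sigma_t) at a frequency."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    return 5.0 * sigma_t


def _edge_valid_mask(freqs: np.ndarray, n_times: int, sfreq: float,
                     n_cycles: float) -> np.ndarray:
    valid = np.ones((len(freqs), n_times), dtype=bool)
    idx = np.arange(n_times)
    for i, f in enumerate(freqs):
        half = int(np.ceil(wavelet_half_support_s(f, n_cycles) * sfreq))
        valid[i] = (idx >= half) & (idx < n_times - half)
    return valid


def _tfr_power(epochs: np.ndarray, sfreq: float, freqs: np.ndarray,
               n_cycles: float) -> np.ndarray:
    """(n_epochs, ch, samples) -> (n_epochs, ch, freqs, times) Morlet power.

    Epochs shorter than the longest wavelet are zero-padded symmetrically
    and cropped back; the affected edge samples lie inside the wavelet
    half support and are flagged invalid by the validity mask anyway.
    """
    n = epochs.shape[-1]
    sigma_max = n_cycles / (2.0 * np.pi * freqs.min())
    need = int(np.ceil(10.0 * sigma_max * sfreq)) + 3
    if need > n:
        pad = (need - n + 1) // 2
        epochs = np.pad(epochs, [(0, 0)] * (epochs.ndim - 1) + [(pad, pad)])
        out = tfr_array_morlet(epochs, sfreq=sfreq, freqs=freqs,
                               n_cycles=n_cycles, output="power", zero_mean=True)
        return out[..., pad:pad + n]
    return tfr_array_morlet(epochs, sfreq=sfreq, freqs=freqs, n_cycles=n_cycles,
                            output="power", zero_mean=True)


def morlet_tfr(signal: np.ndarray, sampling_rate_hz: float,
               freqs: np.ndarray | None = None,
               n_cycles: float = DEFAULT_N_CYCLES,
               t0_s: float = 0.0) -> TimeFrequencyMap:
    """Morlet wavelet power of a channels x samples array."""
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if sampling_rate_hz <= 2.0 * freqs.max():
        raise ValueError("sampling rate must exceed twice the highest frequency")
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    power = _tfr_power(signal[np.newaxis], sampling_rate_hz, freqs, n_cycles)[0]
    times = t0_s + np.arange(signal.shape[1]) / sampling_rate_hz
    valid = _edge_valid_mask(freqs, signal.shape[1], sampling_rate_hz, n_cycles)
    return TimeFrequencyMap(power, freqs, times, sampling_rate_hz, valid)


def baseline_spectrum(tfr: TimeFrequencyMap,
                      window_s: tuple[float, float]) -> np.ndarray:
    """R(c, f): mean power over the (half-open) time window, valid samples
    only; falls back to all samples in the window if none are valid."""
    sel = (tfr.times >= window_s[0]) & (tfr.times < window_s[1])
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    R = np.empty(tfr.power.shape[:2])
    for i in range(len(tfr.freqs)):
        use = sel & tfr.valid[i]
        if not use.any():
            use = sel
        R[:, i] = tfr.power[:, i, use].mean(axis=1)
    return R


def compute_erd(tfr: TimeFrequencyMap, baseline: np.ndarray) -> ErdMap:
    """Elementwise ERD percent; invalid TFR samples stay invalid."""
    R = np.asarray(baseline, dtype=float)
    if np.any(R <= 0):
        raise ValueError("baseline power must be strictly positive at every "
                         "analyzed frequency")
    values = (tfr.power - R[:, :, np.newaxis]) / R[:, :, np.newaxis] * 100.0
    return ErdMap(values, tfr.freqs, tfr.times, tfr.valid.copy())


def trial_alpha_erd(erd: ErdMap, band_hz: tuple[float, float] = ALPHA_BAND,
                    window_s: tuple[float, float] | None = None) -> np.ndarray:
    """Per-channel mean ERD over band bins (inclusive) and valid window
    samples (half-open window)."""
    fsel = (erd.freqs >= band_hz[0] - 1e-9) & (erd.freqs <= band_hz[1] + 1e-9)
    if not fsel.any():
        raise ValueError("band lies outside the frequency axis")
    if window_s is None:
        tsel = np.ones(len(erd.times), dtype=bool)
    else:
        tsel = (erd.times >= window_s[0]) & (erd.times < window_s[1])
    if not tsel.any():
        raise ValueError("empty ERD averaging window")
    vals = erd.values[:, fsel][:, :, tsel]
    valid = erd.valid[fsel][:, tsel]
    if not valid.any():
        raise ValueError("no valid time-frequency samples in the ERD window")
    # average over (freq, time) cells that are valid, per channel
    out = np.array([v[valid].mean() for v in vals])
    return out


def erd_table(trials: TrialSet, channel_names: list[str],
              freqs: np.ndarray | None = None,
              band_hz: tuple[float, float] = ALPHA_BAND,
              n_cycles: float = DEFAULT_N_CYCLES) -> pd.DataFrame:
    """Single-trial alpha ERD for every epoch (bad trials carry good=False).

    Returns a tidy frame: trial, channel, condition, erd_percent, good.
    The baseline R(f, c) is computed per trial from that trial's own
    pre-trial window.
    """
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if not trials.trials:
        return pd.DataFrame(columns=["trial", "channel", "condition",
                                     "erd_percent", "good"])
    fs = trials.sampling_rate_hz
    epochs = np.stack([t.data for t in trials.trials])
    power = _tfr_power(epochs, fs, freqs, n_cycles)
    n_times = epochs.shape[2]
    valid = _edge_valid_mask(freqs, n_times, fs, n_cycles)
    # epoch time axis: 0 corresponds to onset - pre_s
    times = np.arange(n_times) / fs - trials.pre_s
    rows = []
    for k, t in enumerate(trials.trials):
        tfr = TimeFrequencyMap(power[k], freqs, times, fs, valid)
        R = baseline_spectrum(tfr, BASELINE_WINDOW_S)
        erd = compute_erd(tfr, R)
        vals = trial_alpha_erd(erd, band_hz, (ERD_WINDOW_START_S, t.duration_s))
        for c, v in zip(channel_names, vals):
            rows.append((k, c, t.condition, float(v), t.good))
    return pd.DataFrame(rows, columns=["trial", "channel", "condition",
                                       "erd_percent", "good"])


def mean_erd_by_condition(table: pd.DataFrame) -> pd.DataFrame:
    """Mean alpha ERD per condition x channel over good trials."""
    good = table[table.good]
    return (good.groupby(["condition", "channel"], as_index=False)
            .erd_percent.mean())
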