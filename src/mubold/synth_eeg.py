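"""Synthetic sensorimotor EEG with condition-dependent alpha desynchronization.

The model is deliberately minimal: each electrode (C3, C4) carries a single
alpha-band sinusoid whose amplitude envelope is modulated by the paradigm,
plus broadband 1/f background noise.  Contralateral task trials suppress
band power by a target event-related desynchronization (ERD) percentage;
ipsilateral trials by a fraction of it.  Instruction and inter-trial
periods inherit the block's condition at 50 % modulation depth, so the
trial-locked ERD (trial window vs. the immediately preceding baseline
window) is planted exactly while block-level power still differs from rest.

On top of the task modulation, each electrode's envelope carries an
independent infra-slow stochastic amplitude process (log-normal, ~15 s
correlation time): the spontaneous waxing and waning of the mu rhythm.
This is what gives continuous alpha power information beyond the task
boxcar — without it the two electrodes' condition-masked power series
would be nearly collinear and an EEG-informed model would have nothing to
exploit — and it produces realistic trial-to-trial ERD variability.

Because band power scales with amplitude squared, an ERD of e percent
corresponds to an amplitude factor sqrt(1 + e/100).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import (
    CONTRALATERAL,
    IPSILATERAL,
    EEGRecording,
    Paradigm,
    condition_hand,
)

ALPHA_BAND = (8.0, 13.5)

#: Fraction of the contralateral ERD planted on the ipsilateral electrode.
#: Ipsilateral desynchronization is reported as present but weaker; its
#: magnitude is a modeling assumption, not a measured quantity.
DEFAULT_IPSI_FRACTION = 0.4

#: Modulation depth of instruction / inter-trial periods relative to trials.
BLOCK_DEPTH = 0.5

#: Spontaneous amplitude process: log-amplitude SD and correlation time.
#: sigma = 0.25 gives a band-power coefficient of variation of ~0.5,
#: typical of ongoing sensorimotor alpha.
DEFAULT_AMP_JITTER_SD = 0.25
DEFAULT_AMP_JITTER_TAU_S = 15.0


def _erd_to_amplitude(e_percent: float) -> float:
    """Amplitude scale factor producing an ERD of e percent (power ~ amp^2)."""
    if e_percent <= -100:
        raise ValueError("ERD percent must be > -100")
    return float(np.sqrt(1.0 + e_percent / 100.0))


def modulation_envelope(
    paradigm: Paradigm,
    erd_percent: dict[str, float],
    electrode: str,
    sampling_rate_hz: float,
    ipsi_fraction: float = DEFAULT_IPSI_FRACTION,
    run: int = 0,
) -> np.ndarray:
    """Amplitude envelope (relative to rest = 1) for one electrode.

    Block periods (instruction + ITIs) sit at 50 % ERD depth; trial windows
    multiply in the full planted ERD on top of the block level, so the
    trial-vs-pre-trial power ratio equals 1 + e/100 exactly.
    """
    r = paradigm.runs[run]
    n = int(round(r.run_length_s * sampling_rate_hz))
    env = np.ones(n)
    for block in paradigm.task_blocks(run):
        e = erd_percent.get(block.label, 0.0)
        hand = condition_hand(block.label)
        if CONTRALATERAL[hand] != electrode:
            if IPSILATERAL[hand] != electrode:
                continue
            e = ipsi_fraction * e
        i0 = int(np.floor(block.onset * sampling_rate_hz))
        i1 = int(np.floor(block.end * sampling_rate_hz))
        env[i0:i1] = _erd_to_amplitude(BLOCK_DEPTH * e)
    for trial in r.trials:
        e = erd_percent.get(trial.label, 0.0)
        hand = condition_hand(trial.label)
        if CONTRALATERAL[hand] != electrode:
            if IPSILATERAL[hand] != electrode:
                continue
            e = ipsi_fraction * e
        i0 = int(np.floor(trial.onset * sampling_rate_hz))
        i1 = int(np.floor(trial.end * sampling_rate_hz))
        env[i0:i1] *= _erd_to_amplitude(e)
    return env


def stochastic_amplitude(
    n: int,
    sampling_rate_hz: float,
    rng: np.random.Generator,
    jitter_sd: float = DEFAULT_AMP_JITTER_SD,
    tau_s: float = DEFAULT_AMP_JITTER_TAU_S,
) -> np.ndarray:
    """Unit-mean log-normal amplitude process with Gaussian-kernel temporal
    smoothing of width tau: exp(sigma * g(t) - sigma^2 / 2) with g ~ N(0,1)."""
    if jitter_sd == 0:
        return np.ones(n)
    g = gaussian_filter1d(rng.standard_normal(n), tau_s * sampling_rate_hz,
                          mode="reflect")
    s = g.std()
    if s > 0:
        g = g / s
    return np.exp(jitter_sd * g - jitter_sd**2 / 2.0)


def alpha_envelopes(
    paradigm: Paradigm,
    erd_percent: dict[str, float],
    sampling_rate_hz: float,
    seed: int,
    ipsi_fraction: float = DEFAULT_IPSI_FRACTION,
    jitter_sd: float = DEFAULT_AMP_JITTER_SD,
    jitter_tau_s: float = DEFAULT_AMP_JITTER_TAU_S,
    run: int = 0,
) -> dict[str, np.ndarray]:
    """Full amplitude envelope (task modulation x spontaneous process) per
    electrode.  The same realization must drive both the EEG synthesis and
    the BOLD forward model, so it is generated once from one seed."""
    rng = np.random.default_rng(seed)
    n = int(round(paradigm.runs[run].run_length_s * sampling_rate_hz))
    out = {}
    for electrode in ("C3", "C4"):  # fixed order keeps the draw deterministic
        task = modulation_envelope(paradigm, erd_percent, electrode,
                                   sampling_rate_hz, ipsi_fraction, run)
        out[electrode] = task * stochastic_amplitude(n, sampling_rate_hz, rng,
                                                     jitter_sd, jitter_tau_s)
    return out


def pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise with the requested standard
    deviation, built by spectral shaping of white noise."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_eeg(
    paradigm: Paradigm,
    erd_percent: dict[str, float],
    seed: int,
    alpha_hz: float = 10.0,
    sampling_rate_hz: float = 250.0,
    noise_sd: float = 2.0,
    alpha_amp_uv: float = 10.0,
    ipsi_fraction: float = DEFAULT_IPSI_FRACTION,
    jitter_sd: float = DEFAULT_AMP_JITTER_SD,
    jitter_tau_s: float = DEFAULT_AMP_JITTER_TAU_S,
    envelopes: dict[str, np.ndarray] | None = None,
    run: int = 0,
) -> EEGRecording:
    """Simulate a C3/C4 recording for one run of the paradigm.

    Parameters
    ----------
    erd_percent
        Mapping condition -> planted contralateral trial ERD in percent
        (negative = desynchronization).  Values must be > -100.
    alpha_hz
        Carrier frequency; values outside the alpha band raise a warning.
    noise_sd
        Standard deviation (microvolts) of the broadband 1/f background.
    alpha_amp_uv
        Resting mean amplitude of the alpha carrier in microvolts.
    envelopes
        Precomputed per-electrode amplitude envelopes (from
        :func:`alpha_envelopes`); generated from the seed when omitted.
    """
    if sampling_rate_hz < 100.0:
        raise ValueError("sampling rate must be >= 100 Hz (2 x 40 Hz with margin)")
    if not (ALPHA_BAND[0] <= alpha_hz <= ALPHA_BAND[1]):
        warnings.warn(f"alpha carrier {alpha_hz} Hz lies outside {ALPHA_BAND}",
                      stacklevel=2)
    for e in erd_percent.values():
        if e <= -100:
            raise ValueError("ERD percent values must be > -100")
    rng = np.random.default_rng(seed)
    if envelopes is None:
        envelopes = alpha_envelopes(paradigm, erd_percent, sampling_rate_hz,
                                    seed=seed + 1, ipsi_fraction=ipsi_fraction,
                                    jitter_sd=jitter_sd, jitter_tau_s=jitter_tau_s,
                                    run=run)
    r = paradigm.runs[run]
    n = int(round(r.run_length_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    data = np.empty((2, n))
    for i, electrode in enumerate(("C3", "C4")):
        phase = rng.uniform(0, 2 * np.pi)
        carrier = np.sin(2 * np.pi * alpha_hz * t + phase)
        data[i] = (alpha_amp_uv * envelopes[electrode] * carrier
                   + pink_noise(n, noise_sd, rng))
    return EEGRecording(channel_names=["C3", "C4"], sampling_rate_hz=sampling_rate_hz,
                        data=data, t0_s=0.0)


def analytic_alpha_power(
    paradigm: Paradigm,
    erd_percent: dict[str, float],
    sampling_rate_hz: float,
    alpha_amp_uv: float = 10.0,
    ipsi_fraction: float = DEFAULT_IPSI_FRACTION,
    envelopes: dict[str, np.ndarray] | None = None,
    seed: int | None = None,
    jitter_sd: float = 0.0,
    jitter_tau_s: float = DEFAULT_AMP_JITTER_TAU_S,
    run: int = 0,
) -> dict[str, np.ndarray]:
    """Noise-free instantaneous alpha band power (uV^2) per electrode.

    This is the envelope-squared mean power of the carrier, amp^2/2 — the
    quantity the Morlet band-power estimator converges to.  Used by the
    BOLD forward model (pass the same ``envelopes`` realization that drove
    the EEG) and by reduced-scale simulations that skip the carrier +
    wavelet round trip (deterministic when ``jitter_sd`` is 0).
    """
    if envelopes is None:
        envelopes = alpha_envelopes(paradigm, erd_percent, sampling_rate_hz,
                                    seed=0 if seed is None else seed,
                                    ipsi_fraction=ipsi_fraction,
                                    jitter_sd=jitter_sd,
                                    jitter_tau_s=jitter_tau_s, run=run)
    return {e: 0.5 * alpha_amp_uv**2 * env**2 for e, env in envelopes.items()}
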