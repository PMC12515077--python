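"""Shared domain containers for the EEG-informed fMRI pipeline.

The experiment is a mixed block/trial motor paradigm: alternating task
blocks (motor execution or kinesthetic motor imagery of the left or right
hand) and rest blocks, recorded with simultaneous EEG (electrodes C3/C4
over the left/right sensorimotor hand areas) and BOLD fMRI (TR = 2 s).

Conventions
-----------
* All times are seconds from run start; intervals are half-open [start, end).
* Sample index for a time t at rate fs is floor(t * fs).
* Voxel indices are 0-based; mm coordinates come from the NIfTI affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The four task conditions: execution/imagery x left/right hand.
TASK_CONDITIONS = ("ME_LH", "ME_RH", "MI_LH", "MI_RH")
REST = "REST"

#: Block/trial timing (seconds).
INSTRUCTION_S = 2.0
TRIAL_S = 3.0
ITI_S = 2.0
TRIALS_PER_BLOCK = 4
TASK_BLOCK_S = INSTRUCTION_S + TRIALS_PER_BLOCK * (TRIAL_S + ITI_S)  # 22 s
REST_BLOCK_S = 16.0

#: Hand -> contralateral sensorimotor electrode.
CONTRALATERAL = {"LH": "C4", "RH": "C3"}
IPSILATERAL = {"LH": "C3", "RH": "C4"}


def condition_hand(condition: str) -> str:
    """'ME_LH' -> 'LH'."""
    return condition.split("_")[1]


def condition_mode(condition: str) -> str:
    """'ME_LH' -> 'ME'."""
    return condition.split("_")[0]


@dataclass(frozen=True)
class Interval:
    """Half-open time interval [onset, onset + duration) tagged with a label."""

    onset: float
    duration: float
    label: str

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class Run:
    """One scanning run: chronological blocks, their trials and instructions."""

    blocks: list[Interval]
    trials: list[Interval]
    instructions: list[Interval]
    run_length_s: float


@dataclass
class Paradigm:
    """Timed block/trial structure of one session (one or more runs)."""

    runs: list[Run]
    tr_s: float = 2.0

    def n_volumes(self, run: int = 0) -> int:
        return int(round(self.runs[run].run_length_s / self.tr_s))

    def task_blocks(self, run: int = 0) -> list[Interval]:
        return [b for b in self.runs[run].blocks if b.label != REST]

    def rest_blocks(self, run: int = 0) -> list[Interval]:
        return [b for b in self.runs[run].blocks if b.label == REST]

    def condition_blocks(self, condition: str, run: int = 0) -> list[Interval]:
        """Blocks whose condition matches exactly (e.g. 'ME_LH') or by
        mode group ('ME' matches both hands; 'REST' matches rest blocks)."""
        if condition == REST:
            return self.rest_blocks(run)
        if condition in ("ME", "MI"):
            return [b for b in self.runs[run].blocks
                    if b.label != REST and condition_mode(b.label) == condition]
        return [b for b in self.runs[run].blocks if b.label == condition]


@dataclass
class EEGRecording:
    """Multichannel EEG in microvolts; data is channels x samples."""

    channel_names: list[str]
    sampling_rate_hz: float
    data: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be channels x samples, one row per channel")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG samples must be finite")

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None
        return self.data[i]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class Bold4D:
    """4D BOLD series on a regular voxel grid; data is x * y * z * volume."""

    data: np.ndarray
    voxel_size_mm: float
    tr_s: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, volume)")
        if self.affine is None:
            # RAS affine centered on the grid
            a = np.eye(4)
            a[:3, :3] *= self.voxel_size_mm
            a[:3, 3] = -self.voxel_size_mm * (np.array(self.data.shape[:3]) - 1) / 2.0
            self.affine = a

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def to_2d(self) -> np.ndarray:
        """volumes x voxels view (C-order voxel raveling)."""
        return self.data.reshape(-1, self.n_volumes).T


@dataclass
class MotionParams:
    """Rigid-body motion estimates: per volume 3 translations (mm) then
    3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion params must be n_volumes x 6")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass
class StatMap:
    """Voxelwise t statistics with degrees of freedom and grid metadata."""

    data: np.ndarray
    df: int
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
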