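"""File-format glue: NIfTI volumes, BIDS-style events, motion text files,
EEG array + sidecar pairs and tab-separated result tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import Bold4D, EEGRecording, MotionParams


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.to_filename(str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def save_bold(bold: Bold4D, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(bold.data, dtype=np.float32), bold.affine)
    img.header.set_zooms((bold.voxel_size_mm,) * 3 + (bold.tr_s,))
    img.to_filename(str(path))
    return path


def load_bold(path: str | Path) -> Bold4D:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    return Bold4D(np.asarray(img.get_fdata(), dtype=float),
                  voxel_size_mm=float(zooms[0]),
                  tr_s=float(zooms[3]) if len(zooms) > 3 else 2.0,
                  affine=img.affine)


def save_motion(motion: MotionParams, path: str | Path) -> Path:
    """6-column whitespace text: translations (mm) then rotations (rad)."""
    path = Path(path)
    np.savetxt(path, motion.params, fmt="%.8f")
    return path


def load_motion(path: str | Path) -> MotionParams:
    return MotionParams(np.loadtxt(path, ndmin=2))


def save_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False, float_format="%.3f")
    return path


def load_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_eeg(rec: EEGRecording, prefix: str | Path) -> tuple[Path, Path]:
    """Numeric array file (.npy, channels x samples) plus a sidecar table
    with channel names, sampling rate and start time."""
    prefix = Path(prefix)
    data_path = prefix.with_suffix(".npy")
    np.save(data_path, rec.data)
    sidecar = prefix.parent / (prefix.name + "_channels.tsv")
    pd.DataFrame({"channel": rec.channel_names,
                  "sampling_rate_hz": rec.sampling_rate_hz,
                  "t0_s": rec.t0_s}).to_csv(sidecar, sep="\t", index=False)
    return data_path, sidecar


def load_eeg(prefix: str | Path) -> EEGRecording:
    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npy"))
    side = pd.read_csv(prefix.parent / (prefix.name + "_channels.tsv"), sep="\t")
    return EEGRecording(channel_names=list(side["channel"]),
                        sampling_rate_hz=float(side["sampling_rate_hz"].iloc[0]),
                        data=data, t0_s=float(side["t0_s"].iloc[0]))


def save_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def save_key_values(values: dict, path: str | Path, decimals: int = 4) -> Path:
    """Machine-readable summary: one 'key<TAB>value' per line; fractions to
    a fixed number of decimals, undefined values written as 'NA'."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in values.items():
            if v is None:
                fh.write(f"{k}\tNA\n")
            elif isinstance(v, float):
                fh.write(f"{k}\t{v:.{decimals}f}\n")
            else:
                fh.write(f"{k}\t{v}\n")
    return path
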