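"""Synthetic BOLD volumes with planted neurovascular coupling.

Forward model: voxels inside a coupled mask follow

    y(v) = baseline + w * z_e,cond(v) + AR(1) noise + slow drift + motion leak

where z_e,cond is the condition-masked, HRF-convolved, TR-sampled alpha
power of electrode e (z-scored over the scan, so the coupling weight w is
expressed in units of the noise SD).  Negative w encodes the hypothesized
coupling: BOLD rises where sensorimotor alpha power falls.  Coupled
regions additionally carry a direct task-evoked response — the canonical
activation of contralateral sensorimotor cortex by hand movement or
imagery, modeled as the HRF-convolved boxcar of the contralateral-hand
condition — since without it a conventional block analysis would have
nothing to detect and could not serve as the reference for overlap
validation.  Uncoupled voxels receive noise + drift only.  Motion
parameters are smooth random walks; a small motion-correlated nuisance
leaks into every voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .core import Bold4D, MotionParams, Paradigm
from .regressors import HrfParams, PowerSeries, canonical_hrf, condition_mask, make_regressor

BASELINE_BOLD = 100.0
#: Drift: sum of cosines with periods >= 200 s (slower than the 128 s
#: high-pass cut-off, so the analysis filter removes it).
DRIFT_PERIODS_S = (200.0, 300.0, 500.0)


@dataclass
class GroundTruth:
    """Planted coupling layout and noise parameters for the simulator."""

    grid_dims: tuple[int, int, int] = (20, 20, 12)
    voxel_size_mm: float = 2.0
    coupled_masks: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    coupling_weight: dict[tuple[str, str], float] = field(default_factory=dict)
    task_weight: dict[tuple[str, str], float] = field(default_factory=dict)
    ar1_phi: float = 0.3
    noise_sd: float = 1.0
    drift_amp: float = 1.0
    motion_amp: float = 0.1

    def __post_init__(self) -> None:
        if not (-1.0 < self.ar1_phi < 1.0):
            raise ValueError("ar1_phi must lie in (-1, 1)")
        occupancy_c3 = np.zeros(self.grid_dims, dtype=bool)
        occupancy_c4 = np.zeros(self.grid_dims, dtype=bool)
        for (electrode, _), mask in self.coupled_masks.items():
            if mask.shape != tuple(self.grid_dims):
                raise ValueError("coupled mask shape must match grid_dims")
            occ = occupancy_c3 if electrode == "C3" else occupancy_c4
            occ |= mask
        if np.any(occupancy_c3 & occupancy_c4):
            raise ValueError("C3 and C4 coupled masks must be disjoint")

    def any_coupled(self) -> np.ndarray:
        out = np.zeros(self.grid_dims, dtype=bool)
        for mask in self.coupled_masks.values():
            out |= mask
        return out


def _box_mask(grid: tuple[int, int, int], x: slice, y: slice, z: slice) -> np.ndarray:
    m = np.zeros(grid, dtype=bool)
    m[x, y, z] = True
    return m


def default_ground_truth(
    grid_dims: tuple[int, int, int] = (20, 20, 12),
    me_weight: float = -0.5,
    mi_weight: float = -0.3,
    me_task_weight: float = 0.5,
    mi_task_weight: float = 0.35,
    **kwargs,
) -> GroundTruth:
    """Default layout: C3 (left-hemisphere electrode) couples to left-grid
    boxes, C4 to mirrored right-grid boxes; ME and MI get separate boxes.
    Box sizes scale with the grid.  Coupled regions also respond directly
    to the contralateral-hand task (imagery more weakly than execution)."""
    nx, ny, nz = grid_dims
    dx, dy, dz = max(nx // 5, 2), max(ny // 5, 2), max(nz // 3, 2)
    x_left = slice(nx // 8, nx // 8 + dx)
    x_right = slice(nx - nx // 8 - dx, nx - nx // 8)
    y_me = slice(ny // 2, ny // 2 + dy)
    y_mi = slice(ny // 8, ny // 8 + dy)
    z_mid = slice(nz // 3, nz // 3 + dz)
    masks = {
        ("C3", "ME"): _box_mask(grid_dims, x_left, y_me, z_mid),
        ("C4", "ME"): _box_mask(grid_dims, x_right, y_me, z_mid),
        ("C3", "MI"): _box_mask(grid_dims, x_left, y_mi, z_mid),
        ("C4", "MI"): _box_mask(grid_dims, x_right, y_mi, z_mid),
    }
    weights = {k: (me_weight if k[1] == "ME" else mi_weight) for k in masks}
    task = {k: (me_task_weight if k[1] == "ME" else mi_task_weight)
            for k in masks}
    return GroundTruth(grid_dims=grid_dims, coupled_masks=masks,
                       coupling_weight=weights, task_weight=task, **kwargs)


def build_truth_regressors(
    paradigm: Paradigm,
    alpha_power: dict[str, PowerSeries],
    n_volumes: int,
    tr_s: float = 2.0,
    hrf_params: HrfParams = HrfParams(),
    run: int = 0,
) -> dict[tuple[str, str], np.ndarray]:
    """The simulator's coupling regressors: masked alpha power, causally
    HRF-convolved and TR block-averaged, then z-scored over the scan."""
    out = {}
    for electrode, series in alpha_power.items():
        hrf = canonical_hrf(1.0 / series.sampling_rate_hz, hrf_params)
        for cond in ("ME", "MI"):
            masked = condition_mask(series, paradigm, cond, run)
            col = make_regressor(masked, hrf, n_volumes, tr_s,
                                 highpass_cutoff_s=None, center=False)
            sd = col.std()
            out[(electrode, cond)] = (col - col.mean()) / sd if sd > 0 else col - col.mean()
    return out


#: Electrode -> contralateral hand (C3 sits over the left hand area's
#: hemisphere and serves the right hand).
ELECTRODE_HAND = {"C3": "RH", "C4": "LH"}


def build_task_regressors(
    paradigm: Paradigm,
    n_volumes: int,
    tr_s: float = 2.0,
    hrf_params: HrfParams = HrfParams(),
    run: int = 0,
) -> dict[tuple[str, str], np.ndarray]:
    """Task-evoked BOLD regressors for the coupled regions: the
    HRF-convolved boxcar of the contralateral-hand condition, TR
    block-averaged and z-scored over the scan."""
    from .glm import block_condition_columns

    cols = block_condition_columns(paradigm, n_volumes, tr_s, hrf_params,
                                   highpass_cutoff_s=None, run=run)
    out = {}
    for electrode, hand in ELECTRODE_HAND.items():
        for mode in ("ME", "MI"):
            col = cols[f"{mode}_{hand}"]
            sd = col.std()
            out[(electrode, mode)] = (col - col.mean()) / sd if sd > 0 else col
    return out


def simulate_motion(n_volumes: int, motion_amp: float,
                    rng: np.random.Generator) -> MotionParams:
    """Smooth random-walk rigid-body parameters (3 translations mm, 3
    rotations rad), zero at the first volume, RMS excursion ~ motion_amp."""
    steps = rng.standard_normal((n_volumes, 6))
    walk = np.cumsum(steps, axis=0) / np.sqrt(max(n_volumes, 1))
    # light smoothing to mimic slow drifts of the head
    kernel = np.ones(5) / 5.0
    for j in range(6):
        walk[:, j] = np.convolve(walk[:, j], kernel, mode="same")
    walk -= walk[0]
    return MotionParams(walk * motion_amp)


def simulate_bold(
    paradigm: Paradigm,
    alpha_power: dict[str, PowerSeries],
    truth: GroundTruth,
    seed: int,
    motion_amp: float | None = None,
    tr_s: float | None = None,
    hrf_params: HrfParams = HrfParams(),
    run: int = 0,
) -> tuple[Bold4D, MotionParams]:
    """Simulate one scan of 4D BOLD plus its motion parameters."""
    tr = paradigm.tr_s if tr_s is None else tr_s
    n_volumes = int(round(paradigm.runs[run].run_length_s / tr))
    for series in alpha_power.values():
        if series.n_samples + 0.5 < n_volumes * tr * series.sampling_rate_hz:
            raise ValueError("alpha power series does not cover the run")
    rng = np.random.default_rng(seed)
    n_voxels = int(np.prod(truth.grid_dims))
    regs = build_truth_regressors(paradigm, alpha_power, n_volumes, tr,
                                  hrf_params, run)

    y = np.full((n_volumes, n_voxels), BASELINE_BOLD)
    # AR(1) noise with stationary marginal SD = noise_sd
    if truth.noise_sd > 0:
        innov_sd = truth.noise_sd * np.sqrt(1.0 - truth.ar1_phi**2)
        w = rng.standard_normal((n_volumes, n_voxels)) * innov_sd
        y += lfilter([1.0], [1.0, -truth.ar1_phi], w, axis=0)
    # slow cosine drift, random per-voxel loading
    if truth.drift_amp > 0:
        t = np.arange(n_volumes) * tr
        basis = np.column_stack([np.cos(2 * np.pi * t / p) for p in DRIFT_PERIODS_S])
        basis /= basis.std(axis=0)
        y += basis @ (rng.standard_normal((basis.shape[1], n_voxels))
                      * truth.drift_amp / np.sqrt(basis.shape[1]))
    amp = truth.motion_amp if motion_amp is None else motion_amp
    motion = simulate_motion(n_volumes, amp, rng)
    if amp > 0 and truth.noise_sd > 0:
        mz = motion.params - motion.params.mean(axis=0)
        sd = mz.std(axis=0)
        mz = np.divide(mz, sd, out=np.zeros_like(mz), where=sd > 0)
        y += mz @ (rng.standard_normal((6, n_voxels)) * 0.1 * truth.noise_sd)
    # planted neurovascular coupling and direct task-evoked activation
    task_regs = (build_task_regressors(paradigm, n_volumes, tr, hrf_params, run)
                 if any(truth.task_weight.values()) else {})
    for key, mask in truth.coupled_masks.items():
        w_c = truth.coupling_weight.get(key, 0.0)
        if w_c != 0.0 and key in regs:
            y[:, mask.ravel()] += w_c * regs[key][:, np.newaxis]
        w_t = truth.task_weight.get(key, 0.0)
        if w_t != 0.0:
            y[:, mask.ravel()] += w_t * task_regs[key][:, np.newaxis]
    data = y.T.reshape(truth.grid_dims + (n_volumes,))
    bold = Bold4D(data=data, voxel_size_mm=truth.voxel_size_mm, tr_s=tr)
    return bold, motion


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float,
                    voxel_size_mm: float) -> np.ndarray:
    """Separable 3D Gaussian smoothing, sigma = FWHM / (2 sqrt(2 ln 2)) per
    axis in voxel units, reflecting at the edges; FWHM 0 is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return np.array(volume, dtype=float, copy=True)
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    return gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma_vox,
                           mode="reflect")


def smooth_bold(bold: Bold4D, fwhm_mm: float) -> Bold4D:
    """Apply the 3D smoother to every volume."""
    out = np.empty_like(bold.data)
    for v in range(bold.n_volumes):
        out[..., v] = gaussian_smooth(bold.data[..., v], fwhm_mm, bold.voxel_size_mm)
    return Bold4D(out, bold.voxel_size_mm, bold.tr_s, bold.affine.copy())
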