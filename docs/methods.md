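# Methods

This note documents the models, defaults and numerical choices behind
`mubold`, and what the synthetic validation does and does not establish.

## Paradigm

A mixed block/trial design. Task blocks last 22 s: a 2 s instruction,
then four 3 s trials each followed by a 2 s inter-trial interval (ITI).
Rest blocks last 16 s and alternate with task blocks. Four task
conditions — execution (ME) and kinesthetic imagery (MI) of the left and
right hand — each occur `blocks_per_condition` times per run in a
randomized, balanced order constrained so that the i-th ME block of a
hand precedes the i-th MI block of the same hand (implemented by
splitting randomized block slots per hand and filling them alternately
ME, MI, …). Runs are padded with trailing rest to an integer multiple of
the TR (2 s) or to a requested volume count. All intervals are half-open
`[onset, end)`; sample index = `floor(t × rate)`.

## Synthetic EEG

Each electrode (C3, C4) carries a single 10 Hz sinusoid whose amplitude
envelope is the product of three factors:

1. **Task modulation.** During a task block the contralateral electrode's
   amplitude drops to `sqrt(1 + 0.5·e/100)` (instruction and ITIs; 50 %
   modulation depth) and within trials it is further multiplied by
   `sqrt(1 + e/100)`, where `e` is the planted ERD in percent. Because
   power is quadratic in amplitude, the trial-to-pre-trial power ratio is
   exactly `1 + e/100`, so the trial estimator is unbiased for the
   planted value while block-level power still differs from rest. The
   ipsilateral electrode receives `0.4·e` (ipsilateral desynchronization
   is real but weaker; 0.4 is an assumption, configurable).
2. **Spontaneous amplitude process.** A unit-mean log-normal process
   `exp(σ·g(t) − σ²/2)` with Gaussian-smoothed `g` (correlation time
   15 s, σ = 0.25, giving a band-power coefficient of variation ≈ 0.5).
   This is the waxing and waning of the mu rhythm at infra-slow
   timescales. It matters twice: it supplies the electrode-specific
   variance that makes an EEG-informed regressor informative beyond the
   task boxcar (without it the C3 and C4 condition-masked power series
   are collinear at r ≈ 0.99 and the lateralized contrasts have almost no
   differential signal), and it produces realistic trial-to-trial ERD
   variability (single-trial SD of order 10 points).
3. **Resting amplitude**, 10 µV.

Broadband 1/f (spectrally shaped Gaussian) noise of SD 2 µV is added.
Defaults for the planted contralateral trial ERD are −16.18 % (right
hand) and −18.58 % (left hand); these are the group means reported for
in-scanner hand imagery, applied to both MI and ME since execution ERD
magnitudes were not reported separately. The same envelope realization
drives both the EEG synthesis and the BOLD forward model (`alpha_envelopes`
is generated once per subject from the subject seed).

## Synthetic BOLD

Grid 20×20×12 voxels at 2 mm (desk-scale but large enough for clusters
and 4 mm smoothing), 400 volumes at TR 2 s. Voxel time series:

```
y = 100 + w · z(electrode, mode) + w_task · b(mode, hand) + AR(1) + drift + motion leak
```

* `z` is the simulator's coupling regressor: the condition-masked,
  causally HRF-convolved, TR block-averaged alpha power of the coupled
  electrode, z-scored over the scan — so `w` is in units of the noise SD.
  Defaults: `w = −0.5` for ME regions, `−0.3` for MI regions (imagery
  effects are weaker); negative sign encodes BOLD rising where alpha
  falls.
* `b` is the direct task-evoked response: the HRF-convolved boxcar of the
  contralateral-hand condition, z-scored; `w_task = +0.5` (ME) / `+0.35`
  (MI). This is the primary physiological activation of contralateral
  sensorimotor cortex; it is what the conventional block analysis
  detects, and without it that analysis could not serve as the reference
  for overlap validation or for the precision-based subject screen.
* Coupled regions are mirrored boxes: C3-coupled boxes in the left half
  of the grid, C4-coupled in the right half (C3 overlies the hemisphere
  serving the right hand), with separate ME and MI boxes.
* Noise is AR(1) with φ = 0.3 and stationary SD 1; drift is a sum of
  cosines with periods 200/300/500 s (all slower than the 128 s high-pass
  cut-off, so the analysis filter must remove them); motion parameters
  are smoothed random walks (amplitude 0.1, giving mean framewise
  displacement ≈ 0.29 mm, near the reported cohort motion), and a small
  motion-correlated nuisance (0.1 × noise SD per standardized motion
  column) leaks into every voxel, to be absorbed by the motion columns of
  the design.

The pipeline applies no spatial smoothing by default
(`smooth_fwhm_mm = 0`): validation is voxel-exact against the planted
masks. The 4 mm FWHM Gaussian smoother (σ = FWHM/(2√(2 ln 2)) per axis,
reflective edges) is implemented and tested as its own operation and can
be enabled in the configuration.

## EEG analysis

Band-pass 0.2–40 Hz (4th-order Butterworth, forward–backward). Epochs
span trial onset −2 s to offset +1 s (half-open; 1500 samples at 250 Hz).
Rejection flags a trial iff any channel's within-epoch sample SD strictly
exceeds 100 µV (population SD, ddof = 0). Morlet power uses 7 cycles at
every frequency (a common default whose ~0.9 s support at 8 Hz is
compatible with the 0.9 s baseline window); samples within half the
wavelet support (5 σ_t) of an edge are flagged invalid and excluded from
averages. Epochs shorter than the longest wavelet are zero-padded
symmetrically before the transform and cropped back — only samples that
the validity mask already excludes are affected. The baseline `R(f, c)`
is computed per trial from that trial's own pre-trial window (the 2 s
pre-trial segment exists precisely to host it); computing it across
trials instead would be a one-line change at the call site. Analysis
bands: alpha 8–13.5 Hz (12 bins) everywhere except the cross-modal
regression, which uses high-alpha 10.5–13.5 Hz (7 bins) — the two bands
are deliberately separate constants, mirroring the split between the
regressor band and the correlate band. No notch filter is applied: the
synthetic data contain no line noise (a gap to document for real-data
use, along with gradient/ballistocardiogram artifact correction, which is
out of scope).

## Regressor construction

Continuous band power uses the same Morlet estimator on the whole
recording, averaged over band bins, with invalid edges filled by the
nearest valid value. Bad-trial spans are imputed on the power series
(after band-averaging) by the pointwise mean of same-condition good
spans; a condition with no good trials leaves its spans unchanged with a
logged warning. Condition masks are block-wide (instruction + trials +
ITIs) and are built from a per-sample label array initialized to REST, so
ME + MI + REST masks partition the run exactly. The canonical HRF is the
SPM-convention double gamma, `g(t; 6, 1) − g(t; 16, 1)/6` on [0, 32] s,
peak-normalized. Convolution is causal; downsampling averages within each
TR interval (anti-aliasing; point sampling is available as an option).
The high-pass residualizes against an orthonormal DCT basis with all
components of period > 128 s (plus the constant), applied identically to
the regressors, the boxcar columns and the BOLD data. EEG columns are
mean-centered per scan but not variance-normalized: the t-contrasts
compare betas across columns in identical (µV²-derived) units, and
rescaling would distort the C3-vs-C4 comparison.

The fixed-effects design concatenates scans: the six EEG columns are
shared labeled columns filled per scan row block; motion (6 per scan) and
intercepts are block-diagonal. Assembly verifies full column rank and
names collinear columns on failure.

## GLM and inference

Ordinary least squares per voxel under an i.i.d. homoscedastic error
model; no autocorrelation correction by default (an AR(1)
Cochrane–Orcutt prewhitening is provided behind a flag). Against AR(1)
noise with φ = 0.3 this modestly inflates |t| for smooth regressors; the
null-calibration check therefore uses white noise, and the planted-effect
criteria are recovery rates, not error rates. All reported contrasts are
one-sided (every hypothesis is directional). Thresholding: voxel passes
iff the upper-tail p of t (residual df) is < 0.001; clusters are
connected components under 18-connectivity (SPM convention; 6 and 26
available) and components smaller than the extent threshold k (default
10; a user parameter, since the random-field-theory "expected voxels per
cluster" is out of scope) are removed. Voxels with numerically zero
residual variance are flagged invalid (NaN) rather than infinite. The
random-effects group model regresses per-subject contrast values on an
intercept plus mean-centered covariates and returns the intercept t.

## Validation metrics

Overlap counts TP/FP/FN between the binarized evaluated map (EEG-informed)
and reference map (block fMRI), optionally intersecting both with an ROI
first. Undefined ratios (zero denominators) are reported as missing, not
zero, so aggregation cannot silently bias. The subject screen computes
each subject's precision of the two imagery contrasts against the
contralateral sensorimotor ROI (voxel threshold only, no extent — the
screen is configurable) and keeps subjects with mean precision strictly
above 15 %. Framewise displacement follows the 50 mm-sphere convention
(sum of absolute backward differences, rotations × 50 mm; first volume
0); the exclusion rule flags mean FD above the group mean plus three
group SDs, one reading of an ambiguous verbal rule, with the multiplier
configurable.

## Cross-modal regression

Samples pair a subject-task's contralateral high-alpha trial ERD (C3 for
right-hand, C4 for left-hand imagery) with the mean first-level t inside
the contralateral sensorimotor ROI over voxels passing p < 0.001
(undefined if none pass; such samples are dropped with a warning). Both
imagery tasks are pooled (up to two samples per subject). Pearson r and
its exact two-sided p from the t transform with n − 2 df.

The default cohort plants *homogeneous* coupling weights, so its
in-pipeline regression is essentially a null check on measurement noise.
The relationship the method is meant to detect — subjects with stronger
desynchronization showing stronger hemodynamic responses — is validated
on a reduced-scale cohort (`simulate_coupling_cohort`): 17 subject-task
samples whose task-activation amplitude grows linearly with the planted
ERD magnitude (0.2 + 0.02 per percent, in noise-SD units), 160 volumes,
a 75-voxel ROI, ERD measured with ±3-point noise. Across 100 such
cohorts the regression recovers a negative r essentially always; only the
sign, not the magnitude, is claimed.

## Problem sizes and determinism

Default study conditions: 6 subjects, one run each of 400 volumes
(800 s), EEG at 250 Hz, 4800 voxels. One master seed; per-subject seeds
are master + subject index, with independent fixed offsets for the
envelope, carrier/noise and BOLD streams — all below 2³¹. Reruns with the
same configuration and seed are bit-identical, including written tables.

## What the synthetic validation shows — and does not

Passing tests establish that the implementation recovers what it plants:
the ERD estimator is calibrated, the regressor chain is linear and
correctly timed, OLS matches an independent solver, the voxel null is
calibrated, planted lateralized coupling is recovered with controlled
false positives, and the overlap/screen/regression logic is exact. The
generator does not model volume conduction or realistic topographies,
gradient/BCG artifacts, physiological (cardiac/respiratory) noise,
multi-band acquisition physics, spatial normalization, or
between-subject anatomical variability; real-data performance therefore
cannot be inferred from these tests. One qualitative behavior does carry
over by construction: imagery effects, planted weaker, yield
high-precision/low-recall overlap and can fail to lateralize for one
hand — the ordering the method exhibits on real recordings.
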