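"""HRF kernel, band power, condition masking, TR resampling, high-pass and
design assembly."""

import numpy as np
import pytest

from mubold.core import EEGRecording, MotionParams
from mubold.regressors import (
    EEG_REGRESSOR_LABELS,
    HrfParams,
    PowerSeries,
    assemble_design,
    canonical_hrf,
    condition_mask,
    continuous_band_power,
    dct_highpass,
    dct_highpass_basis,
    impute_bad_trials,
    make_regressor,
)


class TestCanonicalHrf:
    def test_zero_at_onset_and_unit_peak(self):
        h = canonical_hrf(0.1)
        assert h[0] == pytest.approx(0.0, abs=1e-12)
        assert h.max() == pytest.approx(1.0)

    def test_peak_latency_on_dense_grid(self):
        dt = 0.001
        h = canonical_hrf(dt)
        assert np.argmax(h) * dt == pytest.approx(5.0, abs=0.5)

    def test_single_sign_change_after_peak(self):
        h = canonical_hrf(0.001)
        post = h[np.argmax(h):]
        signs = np.sign(post[np.abs(post) > 1e-12])
        assert np.sum(np.diff(signs) != 0) == 1

    def test_matches_reference_spm_kernel(self):
        """Shape agrees with the independent canonical-HRF implementation
        in nilearn (normalization differs, so compare after peak scaling)."""
        nilearn_glm = pytest.importorskip("nilearn.glm.first_level")
        dt = 0.1
        ours = canonical_hrf(dt)
        ref = nilearn_glm.spm_hrf(t_r=1.0, oversampling=int(1 / dt), time_length=32.0)
        ref = ref / ref.max()
        # nilearn evaluates on a grid offset by one sample; align first
        n = min(len(ours), len(ref) - 1)
        assert np.corrcoef(ours[:n], ref[1:n + 1])[0, 1] > 0.9999
        assert np.allclose(ours[:n], ref[1:n + 1], atol=0.02)

    def test_invalid_dt_raises(self):
        with pytest.raises(ValueError):
            canonical_hrf(0.0)


class TestContinuousBandPower:
    def test_stationary_sinusoid_gives_constant_power(self, sinusoid_recording):
        series = continuous_band_power(sinusoid_recording)
        vals = series["C3"].values
        mid = vals[500:-500]
        assert mid.std() / mid.mean() < 0.05

    def test_amplitude_step_quadruples_power(self):
        fs = 250.0
        t = np.arange(int(40 * fs)) / fs
        amp = np.where(t < 20, 1.0, 2.0)
        sig = amp * np.sin(2 * np.pi * 10 * t)
        rec = EEGRecording(["C3", "C4"], fs, np.vstack([sig, sig]))
        p = continuous_band_power(rec)["C3"].values
        before = p[int(10 * fs):int(18 * fs)].mean()
        after = p[int(24 * fs):int(36 * fs)].mean()
        assert after / before == pytest.approx(4.0, rel=0.05)

    def test_band_bin_count(self):
        assert len(np.arange(8.0, 13.5 + 1e-9, 0.5)) == 12

    def test_missing_electrode_raises(self, sinusoid_recording):
        rec = EEGRecording(["C3"], 250.0, sinusoid_recording.data[:1])
        with pytest.raises(KeyError):
            continuous_band_power(rec, ("C3", "C4"))


class TestConditionMask:
    def test_partition_sums_to_original(self, small_paradigm, rng):
        fs = 250.0
        n = int(small_paradigm.runs[0].run_length_s * fs)
        series = PowerSeries("C3", fs, rng.random(n))
        parts = [condition_mask(series, small_paradigm, c).values
                 for c in ("ME", "MI", "REST")]
        assert np.array_equal(sum(parts), series.values)

    def test_task_block_retains_5500_samples(self, small_paradigm):
        fs = 250.0
        n = int(small_paradigm.runs[0].run_length_s * fs)
        series = PowerSeries("C3", fs, np.ones(n))
        me = condition_mask(series, small_paradigm, "ME")
        # 2 ME blocks x 22 s x 250 Hz
        assert int(me.values.sum()) == 2 * 5500

    def test_rest_mask_zero_where_series_zero_in_rest(self, small_paradigm):
        fs = 100.0
        n = int(small_paradigm.runs[0].run_length_s * fs)
        values = np.ones(n)
        for b in small_paradigm.rest_blocks():
            values[int(b.onset * fs):int(b.end * fs)] = 0.0
        rest = condition_mask(PowerSeries("C3", fs, values), small_paradigm, "REST")
        assert np.all(rest.values == 0.0)


class TestImputation:
    def _trials(self, paradigm, fs=100.0, bad_index=None):
        from mubold.eeg_features import TrialEpoch, TrialSet
        eps = []
        for k, t in enumerate(paradigm.runs[0].trials):
            eps.append(TrialEpoch(t.label, t.onset, t.duration,
                                  int((t.onset - 2) * fs),
                                  np.zeros((2, int(6 * fs))),
                                  good=(k != bad_index)))
        return TrialSet(eps, fs)

    def test_no_bad_trials_identity(self, small_paradigm, rng):
        fs = 100.0
        n = int(small_paradigm.runs[0].run_length_s * fs)
        series = PowerSeries("C3", fs, rng.random(n))
        out = impute_bad_trials(series, self._trials(small_paradigm), small_paradigm)
        assert np.array_equal(out.values, series.values)

    def test_bad_trial_replaced_by_condition_mean(self, small_paradigm):
        """A bad trial's span becomes the pointwise mean of the good
        same-condition spans (here constants 1 and 3 -> 2)."""
        fs = 100.0
        n = int(small_paradigm.runs[0].run_length_s * fs)
        trials = self._trials(small_paradigm, fs, bad_index=None)
        cond = trials.trials[0].condition
        same = [t for t in trials.trials if t.condition == cond]
        assert len(same) == 4
        values = np.zeros(n)
        spans = [(int(t.onset_s * fs), int(t.onset_s * fs) + int(3 * fs))
                 for t in same]
        for (i0, i1), v in zip(spans, (5.0, 1.0, 3.0, 2.0)):
            values[i0:i1] = v
        bad_idx = trials.trials.index(same[0])
        trials.trials[bad_idx].good = False
        out = impute_bad_trials(PowerSeries("C3", fs, values), trials,
                                small_paradigm)
        i0, i1 = spans[0]
        assert np.allclose(out.values[i0:i1], 2.0)  # mean of 1, 3, 2
        # untouched elsewhere
        assert np.array_equal(out.values[i1:], values[i1:])

    def test_no_good_trials_leaves_span(self, small_paradigm, caplog):
        fs = 100.0
        n = int(small_paradigm.runs[0].run_length_s * fs)
        trials = self._trials(small_paradigm, fs)
        cond = trials.trials[0].condition
        for t in trials.trials:
            if t.condition == cond:
                t.good = False
        series = PowerSeries("C3", fs, np.ones(n))
        with caplog.at_level("WARNING"):
            out = impute_bad_trials(series, trials, small_paradigm)
        assert np.array_equal(out.values, series.values)


class TestMakeRegressor:
    def test_zero_series_gives_zero_column(self):
        fs = 50.0
        series = PowerSeries("C3", fs, np.zeros(int(100 * fs)))
        col = make_regressor(series, canonical_hrf(1 / fs), 50)
        assert np.allclose(col, 0.0)

    def test_impulse_yields_hrf_at_tr(self):
        """An impulse input reproduces the HRF sampled at the volume grid
        (point sampling, no high-pass, up to centering)."""
        fs = 50.0
        tr = 2.0
        n = int(120 * fs)
        values = np.zeros(n)
        values[0] = fs  # unit-area impulse
        series = PowerSeries("C3", fs, values)
        hrf = canonical_hrf(1 / fs)
        col = make_regressor(series, hrf, 60, tr, highpass_cutoff_s=None,
                             downsample="point", center=False)
        expected = np.zeros(60)
        idx = (np.arange(60) * tr * fs).astype(int)
        expected[idx < len(hrf)] = hrf[idx[idx < len(hrf)]]
        assert np.allclose(col, expected, atol=1e-9)

    def test_slow_cosine_removed_by_highpass(self):
        fs = 10.0
        tr = 2.0
        n_vol = 300
        t = np.arange(int(n_vol * tr * fs)) / fs
        series = PowerSeries("C3", fs, 5.0 + np.cos(2 * np.pi * t / 300.0))
        col = make_regressor(series, canonical_hrf(1 / fs), n_vol, tr,
                             highpass_cutoff_s=128.0)
        slow = np.cos(2 * np.pi * np.arange(n_vol) * tr / 300.0)
        r = np.corrcoef(col, slow)[0, 1]
        assert abs(r) < 0.05

    def test_linearity(self, rng):
        fs = 20.0
        n_vol = 100
        n = int(n_vol * 2 * fs)
        x, y = rng.random(n), rng.random(n)
        hrf = canonical_hrf(1 / fs)
        mk = lambda v: make_regressor(PowerSeries("C3", fs, v), hrf, n_vol)  # noqa: E731
        combo = mk(2.0 * x + 3.0 * y)
        assert np.allclose(combo, 2.0 * mk(x) + 3.0 * mk(y), atol=1e-9)

    def test_shift_covariance_one_tr(self, rng):
        """Delaying the input by one TR shifts the column by one row
        (checked without the high-pass projection, which is a fixed basis
        and therefore not itself shift-covariant)."""
        fs = 20.0
        tr = 2.0
        n_vol = 100
        n = int(n_vol * tr * fs)
        x = rng.random(n)
        shifted = np.concatenate([np.zeros(int(tr * fs)), x])[:n]
        hrf = canonical_hrf(1 / fs)
        a = make_regressor(PowerSeries("C3", fs, x), hrf, n_vol, tr,
                           highpass_cutoff_s=None, center=False)
        b = make_regressor(PowerSeries("C3", fs, shifted), hrf, n_vol, tr,
                           highpass_cutoff_s=None, center=False)
        assert np.allclose(b[1:], a[:-1], atol=1e-6)

    def test_short_series_raises(self):
        series = PowerSeries("C3", 10.0, np.zeros(100))
        with pytest.raises(ValueError):
            make_regressor(series, canonical_hrf(0.1), 500)


class TestHighpassBasis:
    def test_basis_periods_exceed_cutoff(self):
        n, tr, cutoff = 200, 2.0, 128.0
        C = dct_highpass_basis(n, tr, cutoff)
        K = C.shape[1] - 1
        assert 2 * n * tr / K > cutoff
        assert 2 * n * tr / (K + 1) <= cutoff

    def test_residual_orthogonal_to_basis(self, rng):
        x = rng.random(150)
        C = dct_highpass_basis(150, 2.0, 128.0)
        r = dct_highpass(x, 2.0, 128.0)
        assert np.allclose(C.T @ r, 0.0, atol=1e-9)


class TestAssembleDesign:
    def _sets(self, n_scans, n_vol, rng):
        sets = [{lab: rng.random(n_vol) for lab in EEG_REGRESSOR_LABELS}
                for _ in range(n_scans)]
        motion = [MotionParams(rng.random((n_vol, 6)) * 0.1)
                  for _ in range(n_scans)]
        return sets, motion

    def test_single_scan_shape(self, rng):
        sets, motion = self._sets(1, 400, rng)
        d = assemble_design(sets, motion)
        assert d.X.shape == (400, 6 + 6 + 1)
        assert d.labels[:6] == list(EEG_REGRESSOR_LABELS)

    def test_two_scans_block_structure(self, rng):
        sets, motion = self._sets(2, 100, rng)
        d = assemble_design(sets, motion)
        assert d.X.shape == (200, 6 + 12 + 2)
        i0 = d.labels.index("intercept_scan0")
        i1 = d.labels.index("intercept_scan1")
        assert np.all(d.X[:100, i0] == 1) and np.all(d.X[100:, i0] == 0)
        assert np.all(d.X[100:, i1] == 1) and np.all(d.X[:100, i1] == 0)
        # motion of scan 1 is zero in scan 0's rows
        m1 = d.labels.index("motion1_scan1")
        assert np.all(d.X[:100, m1] == 0)

    def test_duplicate_regressor_raises_rank_error(self, rng):
        sets, motion = self._sets(1, 50, rng)
        sets[0]["C4-REST"] = sets[0]["C3-ME"].copy()
        with pytest.raises(ValueError, match="collinear"):
            assemble_design(sets, motion)

    def test_mismatched_lengths_raise(self, rng):
        sets, motion = self._sets(1, 50, rng)
        motion[0] = MotionParams(np.zeros((49, 6)))
        with pytest.raises(ValueError):
            assemble_design(sets, motion)
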