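"""OLS engine, t-contrasts, block designs, group models and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mubold.core import MotionParams, StatMap
from mubold.glm import (
    ar1_prewhiten,
    block_condition_columns,
    block_design,
    contrast_vector,
    fit_glm,
    second_level,
    t_contrast,
    threshold_and_cluster,
)
from mubold.regressors import canonical_hrf


def _oracle_ols(Y, X):
    """Independent normal-equations reference."""
    beta = np.linalg.solve(X.T @ X, X.T @ Y)
    resid = Y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    return beta, sigma2, df


class TestFitGlm:
    def test_orthonormal_design_closed_form(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((50, 5)))
        Y = rng.standard_normal((50, 7))
        fit = fit_glm(Y, Q)
        assert np.allclose(fit.betas, Q.T @ Y, atol=1e-10)

    def test_noiseless_recovery(self, rng):
        X = rng.standard_normal((60, 4))
        beta_true = rng.standard_normal((4, 3))
        fit = fit_glm(X @ beta_true, X)
        assert np.allclose(fit.betas, beta_true, atol=1e-8)
        assert np.allclose(fit.sigma2, 0.0, atol=1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_normal_equations_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(20, 100))
        p = int(rng.integers(2, 12))
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, 20))
        fit = fit_glm(Y, X)
        beta_o, sigma2_o, df_o = _oracle_ols(Y, X)
        assert fit.df == df_o
        assert np.allclose(fit.betas, beta_o, rtol=1e-8, atol=1e-10)
        assert np.allclose(fit.sigma2, sigma2_o, rtol=1e-8, atol=1e-12)

    def test_row_mismatch_and_rank_deficiency_raise(self, rng):
        X = rng.standard_normal((30, 3))
        with pytest.raises(ValueError):
            fit_glm(rng.standard_normal((29, 2)), X)
        Xd = np.column_stack([X, X[:, 0]])
        with pytest.raises(ValueError):
            fit_glm(rng.standard_normal((30, 2)), Xd)


class TestTContrast:
    def test_single_column_matches_hand_formula(self, rng):
        X = rng.standard_normal((40, 3))
        Y = rng.standard_normal((40, 5))
        fit = fit_glm(Y, X)
        c = np.array([0.0, 1.0, 0.0])
        t = t_contrast(fit, c)
        xtx_inv = np.linalg.inv(X.T @ X)
        expected = fit.betas[1] / np.sqrt(fit.sigma2 * xtx_inv[1, 1])
        assert np.allclose(t, expected, rtol=1e-10)

    def test_sign_flip_negates_map(self, rng):
        X = rng.standard_normal((40, 3))
        fit = fit_glm(rng.standard_normal((40, 5)), X)
        c = np.array([1.0, -1.0, 0.0])
        assert np.allclose(t_contrast(fit, c), -t_contrast(fit, -c), rtol=1e-12)

    def test_zero_variance_voxel_flagged_invalid(self, rng):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        Y = np.column_stack([X @ np.array([1.0, 2.0]),
                             rng.standard_normal(20)])
        fit = fit_glm(Y, X)
        t = t_contrast(fit, np.array([0.0, 1.0]))
        assert np.isnan(t[0]) and np.isfinite(t[1])

    def test_labeled_contrast_vector(self):
        labels = ["C3-ME", "C4-ME", "intercept"]
        c = contrast_vector(labels, {"C4-ME": 1.0, "C3-ME": -1.0})
        assert np.array_equal(c, [-1.0, 1.0, 0.0])
        with pytest.raises(KeyError):
            contrast_vector(labels, {"nope": 1.0})
        with pytest.raises(ValueError):
            contrast_vector(labels, {"C3-ME": 0.0})

    def test_coupled_voxel_detected_across_seeds(self):
        """A voxel coupled at weight -0.5 to a unit-SD regressor over 400
        volumes with AR(1) noise exceeds |t| > 3.1 in >= 90 % of seeds."""
        from scipy.signal import lfilter
        n = 400
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal(n)
            z = (z - z.mean()) / z.std()
            noise = lfilter([1.0], [1.0, -0.3], rng.standard_normal(n)
                            * np.sqrt(1 - 0.3**2))
            y = -0.5 * z + noise
            X = np.column_stack([z, np.ones(n)])
            t = t_contrast(fit_glm(y, X), np.array([1.0, 0.0]))
            hits += abs(t[0]) > 3.1
        assert hits / n_seeds >= 0.9


class TestBlockDesign:
    def test_column_peak_lags_block_onset(self, small_paradigm):
        cols = block_condition_columns(small_paradigm, tr_s=2.0,
                                       highpass_cutoff_s=None)
        cond = small_paradigm.task_blocks()[0].label
        block = small_paradigm.condition_blocks(cond)[0]
        col = cols[cond]
        peak_t = np.argmax(col) * 2.0
        lag = peak_t - block.onset
        # a 22 s boxcar convolved with the HRF peaks well after onset
        assert 4.0 <= lag <= 20.0

    def test_disjoint_boxcars(self, small_paradigm):
        fs = 10.0
        n = int(small_paradigm.runs[0].run_length_s * fs)
        boxes = {}
        for cond in ("ME_LH", "ME_RH"):
            box = np.zeros(n)
            for b in small_paradigm.condition_blocks(cond):
                box[int(b.onset * fs):int(b.end * fs)] = 1.0
            boxes[cond] = box
        assert boxes["ME_LH"] @ boxes["ME_RH"] == 0.0

    def test_full_design_shape_and_contrast_direction(self, small_paradigm, rng):
        n_vol = small_paradigm.n_volumes()
        motion = MotionParams(rng.random((n_vol, 6)) * 0.05)
        design = block_design(small_paradigm, motion)
        assert design.X.shape == (n_vol, 4 + 6 + 1)
        # planted RH-only activation gives positive "ME RH > ME LH" t
        y = 2.0 * design.column("ME_RH") + rng.standard_normal(n_vol)
        fit = fit_glm(y, design)
        t = t_contrast(fit, {"ME_RH": 1.0, "ME_LH": -1.0})
        assert t[0] > 3.0


class TestSecondLevel:
    def test_identical_maps_flagged_invalid(self):
        maps = np.tile([2.0, 3.0], (6, 1))
        out = second_level(maps)
        assert np.all(np.isnan(out.data))

    def test_orthogonal_covariate_equals_one_sample_t(self, rng):
        """With a covariate orthogonal to the effect, the intercept t
        matches the plain one-sample t-test up to degrees of freedom."""
        n = 12
        maps = rng.standard_normal((n, 30)) + 0.5
        cov = np.arange(n, dtype=float)
        cov = cov - cov.mean()
        out = second_level(maps, pd.DataFrame({"age": cov}))
        # oracle: per-voxel OLS on [1, cov] computed independently
        X = np.column_stack([np.ones(n), cov])
        beta, sigma2, df = _oracle_ols(maps, X)
        xtx_inv = np.linalg.inv(X.T @ X)
        t_oracle = beta[0] / np.sqrt(sigma2 * xtx_inv[0, 0])
        assert np.allclose(out.data, t_oracle, rtol=1e-8)
        # and with no covariate at all, exactly scipy's one-sample t
        out0 = second_level(maps)
        t_scipy = stats.ttest_1samp(maps, 0.0, axis=0).statistic
        assert np.allclose(out0.data, t_scipy, rtol=1e-8)

    def test_group_mean_recovered(self):
        """Planted group effect d = 1 at n = 10: mean estimate within 0.2
        over 200 seeds."""
        means = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            maps = rng.standard_normal((10, 1)) + 1.0
            means.append(maps.mean())
        assert np.mean(means) == pytest.approx(1.0, abs=0.2)

    def test_degenerate_covariates_raise(self, rng):
        maps = rng.standard_normal((8, 5))
        cov = pd.DataFrame({"a": np.ones(8), "b": np.ones(8)})
        with pytest.raises(ValueError):
            second_level(maps, cov)

    def test_too_few_subjects_raise(self, rng):
        with pytest.raises(ValueError):
            second_level(rng.standard_normal((3, 5)),
                         pd.DataFrame({"age": [1.0, 2.0, 3.0]}))


class TestThresholdAndCluster:
    def _map(self, data, df=100):
        return StatMap(np.asarray(data, dtype=float), df=df, affine=np.eye(4))

    def test_all_zero_map_empty_result(self):
        binary, table = threshold_and_cluster(self._map(np.zeros((5, 5, 5))))
        assert not binary.any() and len(table) == 0

    def test_extent_threshold_rule(self):
        data = np.zeros((8, 8, 8))
        data[2:4, 2:4, 2] = 10.0  # 4-voxel blob
        kept, _ = threshold_and_cluster(self._map(data), extent_k=4)
        removed, _ = threshold_and_cluster(self._map(data), extent_k=5)
        assert kept.sum() == 4 and removed.sum() == 0

    def test_edge_touching_blobs_merge_under_18_connectivity(self):
        """Two voxels sharing only an edge are one cluster under
        18-connectivity but two under 6-connectivity."""
        data = np.zeros((5, 5, 5))
        data[1, 1, 1] = 8.0
        data[2, 2, 1] = 8.0  # differs in two indices -> edge neighbor
        _, t18 = threshold_and_cluster(self._map(data), extent_k=1,
                                       connectivity=18)
        _, t6 = threshold_and_cluster(self._map(data), extent_k=1,
                                      connectivity=6)
        assert len(t18) == 1 and len(t6) == 2

    def test_table_sorted_by_peak_and_mm_coordinates(self):
        data = np.zeros((6, 6, 6))
        data[0, 0, 0] = 5.0
        data[4, 4, 4] = 9.0
        binary, table = threshold_and_cluster(self._map(data), extent_k=1)
        assert list(table.peak_t) == [9.0, 5.0]
        assert (table.loc[0, ["peak_x_mm", "peak_y_mm", "peak_z_mm"]] ==
                [4.0, 4.0, 4.0]).all()

    def test_one_sided_threshold(self):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = -50.0  # strongly negative never passes
        binary, _ = threshold_and_cluster(self._map(data), extent_k=1)
        assert not binary.any()


def test_contrast_antisymmetry_on_random_fit(rng):
    """'C3 < C4' and 'C4 < C3' maps are exact negations."""
    X = rng.standard_normal((80, 4))
    fit = fit_glm(rng.standard_normal((80, 50)), X)
    fit.labels = ["C3-ME", "C4-ME", "C3-MI", "C4-MI"]
    a = t_contrast(fit, {"C4-ME": 1.0, "C3-ME": -1.0})
    b = t_contrast(fit, {"C3-ME": 1.0, "C4-ME": -1.0})
    assert np.allclose(a, -b, rtol=1e-12)


def test_ar1_prewhitening_recovers_phi(rng):
    from scipy.signal import lfilter
    n = 2000
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    noise = lfilter([1.0], [1.0, -0.5], rng.standard_normal((n, 3)), axis=0)
    Y = X @ np.array([[1.0, 1.0, 1.0], [0.5, 0.5, 0.5]]) + noise
    _, _, phi = ar1_prewhiten(Y, X)
    assert phi == pytest.approx(0.5, abs=0.07)


def test_fixed_effects_consistency(rng):
    """Concatenating two identical-truth scans shrinks the contrast SE by
    about sqrt(2)."""
    n = 300
    z = rng.standard_normal(n)
    ses = []
    for n_scans in (1, 2):
        X = np.zeros((n * n_scans, 1 + n_scans))
        for s in range(n_scans):
            X[s * n:(s + 1) * n, 0] = z
            X[s * n:(s + 1) * n, 1 + s] = 1.0
        se_runs = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            y = 0.3 * X[:, 0] + r.standard_normal(n * n_scans)
            fit = fit_glm(y, X)
            c = np.zeros(1 + n_scans)
            c[0] = 1.0
            se = np.sqrt(fit.sigma2[0] * (c @ fit.xtx_inv @ c))
            se_runs.append(se)
        ses.append(np.mean(se_runs))
    assert ses[0] / ses[1] == pytest.approx(np.sqrt(2), rel=0.1)
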