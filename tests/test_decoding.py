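"""Ridge decoding, residualization, target classification and latencies."""

import numpy as np
import pytest

from reachkin import decoding as D


class TestSelectRois:
    def test_top_rule_takes_hundred_smallest(self, rng):
        p = rng.permutation(150) / 150.0
        sel = D.select_rois(p, "top", 100)
        assert sel.size == 100
        assert set(np.argsort(p)[:100]) == set(sel)

    def test_fewer_than_requested_returns_all_with_warning(self, rng):
        with pytest.warns(UserWarning):
            sel = D.select_rois(rng.random(80), "top", 100)
        assert sel.size == 80

    def test_threshold_rule(self):
        p = np.array([[0.5, 0.001], [0.2, 0.9], [0.005, 0.5]])
        sel = D.select_rois(p, "threshold", p_threshold=0.01)
        assert np.array_equal(sel, [0, 2])

    def test_no_qualifying_roi_errors(self):
        with pytest.raises(ValueError):
            D.select_rois(np.full(10, 0.9), "threshold")


class TestFitRidge:
    def test_lambda_zero_equals_ols(self, rng):
        x = rng.standard_normal((200, 10))
        y = rng.standard_normal((200, 3))
        w, xm, ym, _ = D.fit_ridge(x, y, 0.0)
        xc, yc = x - x.mean(0), y - y.mean(0)
        w_ols = np.linalg.lstsq(xc, yc, rcond=None)[0]
        assert np.abs(w - w_ols).max() < 1e-10

    def test_huge_lambda_shrinks_weights_to_zero(self, rng):
        x = rng.standard_normal((100, 5))
        y = rng.standard_normal(100)
        w, *_ = D.fit_ridge(x, y, 1e12)
        assert np.abs(w).max() < 1e-6

    def test_auto_lambda_close_to_grid_best(self, rng):
        n, p = 2000, 30
        x = rng.standard_normal((n, p))
        w_true = rng.standard_normal((p, 1))
        y = x @ w_true + 3.0 * rng.standard_normal((n, 1))
        xtr, xte = x[:1000], x[1000:]
        ytr, yte = y[:1000], y[1000:]

        def ve(lam):
            w, xm, ym, _ = D.fit_ridge(xtr, ytr, lam)
            pred = D.ridge_predict(xte, w, xm, ym)
            return 1 - np.sum((yte - pred) ** 2) / np.sum((yte - yte.mean()) ** 2)

        grid = np.logspace(-4, 6, 20)
        best = max(ve(g) for g in grid)
        _, _, _, lam_auto = D.fit_ridge(xtr, ytr, "auto")
        assert ve(lam_auto) >= best - 0.02

    def test_nonfinite_inputs_rejected(self, rng):
        x = rng.standard_normal((50, 4))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            D.fit_ridge(x, rng.standard_normal(50))


class TestJointDecoding:
    def _linear_population(self, rng, n_tr=24, n_bins=20, n_rois=30, n_joints=6,
                           noise=0.05):
        kin = rng.standard_normal((n_tr, n_bins, n_joints)).cumsum(axis=1)
        w = rng.standard_normal((n_joints, n_rois))
        neural = kin @ w + noise * rng.standard_normal((n_tr, n_bins, n_rois))
        return neural, kin

    def test_fold_structure_fifty_folds_each_trial_five_times(self, rng):
        neural, kin = self._linear_population(rng)
        cfg = D.RidgeConfig(seed=0, neural_smoothing_sd_ms=0.0)
        res = D.decode_joint_timeseries(neural, kin, cfg)
        assert res.variance_explained.shape[1] == 50
        counts = np.zeros(neural.shape[0], dtype=int)
        for _rep, _fold, te in res.folds:
            counts[te] += 1
        assert np.all(counts == 5)

    def test_linear_map_recovered_with_low_noise(self, rng):
        neural, kin = self._linear_population(rng)
        cfg = D.RidgeConfig(seed=0, neural_smoothing_sd_ms=0.0)
        res = D.decode_joint_timeseries(neural, kin, cfg)
        assert res.median_ve.min() > 0.95

    def test_trial_shuffle_destroys_decoding(self, rng):
        neural, kin = self._linear_population(rng)
        perm = rng.permutation(neural.shape[0])
        cfg = D.RidgeConfig(seed=0, neural_smoothing_sd_ms=0.0)
        res = D.decode_joint_timeseries(neural[perm], kin, cfg)
        assert res.variance_explained.mean() <= 0.05

    def test_pca_rank_is_ninety_percent_of_neurons(self):
        assert int(np.floor(0.9 * 100)) == 90
        cfg = D.RidgeConfig()
        assert cfg.pca_fraction == 0.9

    def test_invariant_to_orthogonal_rotation_of_features(self, rng):
        neural, kin = self._linear_population(rng)
        q, _ = np.linalg.qr(rng.standard_normal((30, 30)))
        cfg = D.RidgeConfig(seed=0, neural_smoothing_sd_ms=0.0)
        r1 = D.decode_joint_timeseries(neural, kin, cfg)
        r2 = D.decode_joint_timeseries(neural @ q, kin, cfg)
        assert np.abs(r1.variance_explained - r2.variance_explained).max() < 1e-6

    def test_fewer_trials_than_folds_errors(self, rng):
        neural, kin = self._linear_population(rng, n_tr=5)
        with pytest.raises(ValueError):
            D.decode_joint_timeseries(neural, kin, D.RidgeConfig(seed=0))

    def test_lag_augmentation_appends_shifted_copies(self, rng):
        x = rng.standard_normal((2, 30, 4))
        out = D._lag_augment(x, "causal", 10.0)
        assert out.shape == (2, 30, 4 * 11)
        out2 = D._lag_augment(x, "acausal", 10.0)
        assert out2.shape == (2, 30, 4 * 21)
        # a shifted copy reproduces the original trace displaced in time
        assert np.allclose(out[:, 10:, :4], x[:, :20, :])


class TestResidualize:
    def test_residuals_orthogonal_to_regressors(self, rng):
        y = rng.standard_normal((500, 8))
        z = rng.standard_normal((500, 3))
        r = D.residualize(y, z)
        assert np.abs(r.T @ (z - z.mean(0))).max() < 1e-9
        assert np.abs(r.mean(0)).max() < 1e-10

    def test_y_equal_z_gives_zero_residuals(self, rng):
        z = rng.standard_normal((200, 4))
        assert np.abs(D.residualize(z, z)).max() < 1e-10

    def test_idempotent(self, rng):
        y = rng.standard_normal((300, 5))
        z = rng.standard_normal((300, 2))
        r1 = D.residualize(y, z)
        r2 = D.residualize(r1, z)
        assert np.abs(r2 - r1).max() < 1e-12

    def test_rank_deficient_regressors_warn(self, rng):
        z = rng.standard_normal((100, 2))
        z = np.hstack([z, z[:, :1]])
        with pytest.warns(UserWarning):
            D.residualize(rng.standard_normal((100, 3)), z)

    def test_condition_mean_residuals_remove_target_means(self, rng):
        y = rng.standard_normal((40, 10, 3))
        t = np.array(["left", "right"] * 20)
        r = D.residualize_condition_means(y, t)
        for side in ("left", "right"):
            assert np.abs(r[t == side].mean(axis=0)).max() < 1e-12


class TestThresholdCrossing:
    def test_step_trace_interpolates_midway(self):
        t_ms = 10.0 * np.arange(20)
        traces = np.zeros((8, 20))
        traces[:, 10:] = 1.0
        times, thr, degen = D.threshold_crossing_time(traces, t_ms)
        assert not degen and thr == 0.5
        assert np.allclose(times, (t_ms[9] + 5.0) / 1000.0)

    def test_three_bin_excursion_is_discarded(self):
        t_ms = 10.0 * np.arange(30)
        trace = np.zeros((4, 30))
        trace[0, 10:13] = 1.0  # only 3 bins above
        trace[1:, 20:] = 1.0
        times, _, _ = D.threshold_crossing_time(trace, t_ms)
        assert np.isnan(times[0])
        assert np.isfinite(times[1:]).all()

    def test_flat_median_trace_degenerate(self):
        times, _, degen = D.threshold_crossing_time(np.ones((5, 30)),
                                                    10.0 * np.arange(30))
        assert degen and np.isnan(times).all()


class TestClassifyTarget:
    def _separable(self, rng, gap=3.0, n_tr=40, n_bins=30, n_feat=12,
                   onset=10):
        y = np.array(["left", "right"] * (n_tr // 2))
        x = rng.standard_normal((n_tr, n_bins, n_feat))
        axis = rng.standard_normal(n_feat)
        axis /= np.linalg.norm(axis)
        s = np.where(y == "right", 1.0, -1.0)
        x[:, onset:, :] += gap * s[:, None, None] * axis[None, None, :]
        return x, y

    def test_planted_separation_gives_high_late_accuracy(self, rng):
        x, y = self._separable(rng)
        t_ms = 10.0 * np.arange(30) - 100.0
        res = D.classify_target(x, y, t_ms, (0.0, None), seed=0,
                                smoothing_sd_ms=0.0)
        assert res.accuracy_per_bin[12:].mean() > 0.95

    def test_no_signal_accuracy_near_chance(self, rng):
        x = rng.standard_normal((60, 30, 10))
        y = np.array(["left", "right"] * 30)
        t_ms = 10.0 * np.arange(30)
        res = D.classify_target(x, y, t_ms, (0.0, None), seed=0,
                                smoothing_sd_ms=0.0)
        # binomial CI around 0.5 for 60 trials x 30 bins of correlated tests
        assert abs(res.accuracy_per_bin.mean() - 0.5) < 0.12

    def test_projection_normalized_by_90th_percentile(self, rng):
        x, y = self._separable(rng)
        t_ms = 10.0 * np.arange(30)
        res = D.classify_target(x, y, t_ms, (0.0, None), seed=0,
                                smoothing_sd_ms=0.0)
        for side in ("left", "right"):
            vals = res.projections[y == side]
            assert np.isclose(np.percentile(vals, 90.0), 1.0)

    def test_single_class_errors(self, rng):
        x = rng.standard_normal((10, 5, 3))
        y = np.array(["left"] * 10)
        with pytest.raises(ValueError):
            D.classify_target(x, y, 10.0 * np.arange(5))


class TestTimeGeneralization:
    def test_matrix_shape_eleven_by_one_ten(self, rng):
        x, y = self._static(rng)
        t_ms = -100.0 + 10.0 * (0.5 + np.arange(110))
        g = D.time_generalized_accuracy(x, y, t_ms, seed=0, smoothing_sd_ms=0.0)
        assert g.shape == (11, 110)

    def _static(self, rng, n_tr=30):
        y = np.array(["left", "right"] * (n_tr // 2))
        x = rng.standard_normal((n_tr, 110, 8))
        s = np.where(y == "right", 1.0, -1.0)
        x[:, 15:, :2] += 2.5 * s[:, None, None]
        return x, y

    def test_static_code_generalizes_uniformly(self, rng):
        x, y = self._static(rng)
        t_ms = -100.0 + 10.0 * (0.5 + np.arange(110))
        g = D.time_generalized_accuracy(x, y, t_ms, seed=0, smoothing_sd_ms=0.0)
        post_epochs = slice(1, None)
        post_bins = t_ms > 60
        assert g[post_epochs, :][:, post_bins].min() > 0.9


class TestReactionTime:
    def test_zero_offsets_give_perfect_correlation(self, rng):
        rt = rng.uniform(0.15, 0.6, 30)
        # degenerate identity: predicted = rt + 0
        r = np.corrcoef(rt + 0.0, rt)[0, 1]
        assert r == 1.0

    def test_lift_locked_population_recovers_rt(self, rng):
        n_tr, n_bins, n_feat = 40, 80, 30
        t_ms = -200.0 + 10.0 * (0.5 + np.arange(n_bins))
        x = rng.poisson(0.2, (n_tr, n_bins, n_feat)).astype(float)
        x[:, (t_ms > 0) & (t_ms < 150), :] += rng.poisson(
            1.5, (n_tr, ((t_ms > 0) & (t_ms < 150)).sum(), n_feat))
        rt = rng.uniform(0.15, 0.6, n_tr)
        y = np.array(["left", "right"] * (n_tr // 2))
        pred, off, r = D.decode_reaction_time(x, rt, y, t_ms, seed=0)
        assert r > 0.9
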