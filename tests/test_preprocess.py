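"""Binning, smoothing, amplitude rescaling, screening, grouping and PETHs."""

import numpy as np
import pytest

from reachkin import preprocess as P
from reachkin.kinematics import N_ANGLES


def _single_event_activity(t, amp=1.0, offset=0.0, fp=0.0322):
    return P.PopulationActivity([np.array([t])], [np.array([amp])],
                                frame_period=fp, roi_offsets=np.array([offset]))


class TestFractionalBinning:
    def test_single_event_mass_conserved_and_proportional(self):
        # frame [5, 37.2) ms against 10 ms bins: overlaps 5/10/10/7.2 ms
        act = _single_event_activity(0.005)
        b = P.bin_events_fractional(act, np.array([0.0]), (0.0, 50.0))
        masses = b.data[0, 0]
        expect = np.array([5.0, 10.0, 10.0, 7.2, 0.0]) / 32.2
        assert np.allclose(masses, expect, atol=1e-12)
        assert np.isclose(masses.sum(), 1.0)

    def test_zero_event_roi_gives_zero_rows(self):
        act = P.PopulationActivity([np.empty(0)], [np.empty(0)])
        b = P.bin_events_fractional(act, np.zeros(3), (-100.0, 400.0))
        assert b.data.shape == (3, 1, 50)
        assert not b.data.any()

    def test_mass_conservation_many_events(self, rng):
        times = np.sort(rng.uniform(0.1, 0.9, 200))
        amps = rng.lognormal(0, 0.5, 200)
        act = P.PopulationActivity([times], [amps])
        b = P.bin_events_fractional(act, np.array([0.0]), (0.0, 1000.0))
        assert np.isclose(b.data.sum(), amps.sum(), atol=1e-12)

    def test_window_edge_truncation_flagged(self):
        act = _single_event_activity(-0.005)  # frame straddles window start
        b = P.bin_events_fractional(act, np.array([0.0]), (0.0, 50.0))
        assert b.truncated_events == 1
        assert b.data.sum() < 1.0

    def test_half_frame_offset_shifts_binned_trace(self, rng):
        # two ROIs fire in the same frames; offsets differ by half a frame
        fp = 0.0322
        frames = np.arange(0.0, 2.0, fp)
        sel = rng.random(frames.size) < 0.4
        t0 = frames[sel]
        act = P.PopulationActivity(
            [t0, t0 + fp / 2],
            [np.ones(t0.size), np.ones(t0.size)],
            frame_period=fp, roi_offsets=np.array([0.0, fp / 2]),
        )
        b = P.bin_events_fractional(act, np.zeros(1), (0.0, 2000.0))
        a, c = b.data[0, 0], b.data[0, 1]
        lags = np.arange(-4, 5)
        xc = [np.dot(a[4:-4], np.roll(c, -k)[4:-4]) for k in lags]
        assert lags[int(np.argmax(xc))] in (1, 2)  # ~16 ms at 10 ms bins

    def test_window_must_align_to_bins(self):
        act = _single_event_activity(0.0)
        with pytest.raises(ValueError):
            P.bin_events_fractional(act, np.zeros(1), (-105.0, 400.0))


class TestGaussianSmooth:
    def test_constant_series_unchanged(self):
        x = np.full(200, 3.3)
        assert np.allclose(P.gaussian_smooth(x, 35.0), x)

    def test_impulse_kernel_sums_to_one(self):
        x = np.zeros(501)
        x[250] = 1.0
        y = P.gaussian_smooth(x, 35.0)
        assert np.isclose(y.sum(), 1.0)
        assert y[250] == y.max()

    def test_zero_sd_is_identity(self, rng):
        x = rng.standard_normal(100)
        assert np.array_equal(P.gaussian_smooth(x, 0.0), x)

    def test_white_noise_variance_reduced_by_kernel_l2(self, rng):
        x = rng.standard_normal(10_000)
        sd_bins = 35.0 / 10.0
        k = np.exp(-0.5 * (np.arange(-14, 15) / sd_bins) ** 2)
        k /= k.sum()
        expected = np.sum(k**2)
        got = P.gaussian_smooth(x, 35.0).var()
        assert abs(got - expected) / expected < 0.05


class TestAmplitudeRescaling:
    def test_constant_amplitudes_map_to_one(self):
        amps = np.full(100, 4.2)
        scaled, scale, flagged = P.rescale_event_amplitudes(amps)
        assert not flagged
        assert np.allclose(scaled, 1.0)
        assert np.isclose(scale, 4.2)

    def test_scale_invariance(self, rng):
        amps = rng.lognormal(0.5, 0.6, 500)
        s1, _, _ = P.rescale_event_amplitudes(amps)
        s2, _, _ = P.rescale_event_amplitudes(amps * 37.0)
        assert np.allclose(s1, s2, rtol=1e-6)

    def test_lognormal_mode_recovered(self, rng):
        mu, sigma = 0.7, 0.5
        amps = rng.lognormal(mu, sigma, 10_000)
        _, scale, _ = P.rescale_event_amplitudes(amps)
        mode = np.exp(mu - sigma**2)  # analytic log-normal mode
        assert abs(scale - mode) / mode < 0.05

    def test_too_few_events_left_unscaled(self):
        amps = np.array([1.0, 2.0, 3.0])
        scaled, scale, flagged = P.rescale_event_amplitudes(amps)
        assert flagged and scale == 1.0
        assert np.array_equal(scaled, amps)


class TestScreening:
    def test_printed_bound_formula(self):
        # pctile1=10, pctile2=30 -> bounds [0, 40]
        vals = np.linspace(10, 30, 1000)[:, None]
        b = P.percentile_bounds(vals, 0.0, 100.0)
        assert np.isclose(b[0, 0], 0.0) and np.isclose(b[1, 0], 40.0)

    def _angles_with_bad_bins(self, n_bad, n_trials=40, n_bins=50):
        rng = np.random.default_rng(0)
        a = rng.uniform(-1, 1, size=(n_trials, n_bins, N_ANGLES))
        a[0, :n_bad, 0] = 100.0  # far outside everyone's range
        return a

    @pytest.mark.parametrize("n_bad,kept", [(5, True), (6, False)])
    def test_boundary_of_five_bin_rule(self, n_bad, kept):
        a = self._angles_with_bad_bins(n_bad)
        targets = np.array(["left", "right"] * 20)
        res = P.screen_trials(a, targets)
        assert bool(res.retained[0]) is kept
        assert res.out_of_bounds_bins[0] == n_bad
        assert res.retained[1:].all()

    def test_sides_screened_separately(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(-1, 1, (40, 50, N_ANGLES))
        a[np.arange(40) % 2 == 1] += 50.0  # right trials occupy another range
        targets = np.where(np.arange(40) % 2 == 0, "left", "right")
        res = P.screen_trials(a, targets)
        assert res.retained.all()

    def test_screening_idempotent_on_clean_data(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(-1, 1, (60, 50, N_ANGLES))
        targets = np.array(["left", "right"] * 30)
        first = P.screen_trials(a, targets)
        again = P.screen_trials(a[first.retained], targets[first.retained])
        assert again.retained.sum() >= first.retained.sum() - 0

    def test_single_trial_side_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-1, 1, (3, 50, N_ANGLES))
        targets = np.array(["left", "left", "right"])
        with pytest.warns(UserWarning):
            res = P.screen_trials(a, targets)
        assert res.retained[2]  # unscreened side defaults to retained


class TestGroupingAndPeth:
    def _events(self, mts, side="left"):
        n = len(mts)
        lift = np.full(n, 0.6)
        return P.TrialEvents(cue_time=np.full(n, 0.5), lift_time=lift,
                             contact_time=lift + np.asarray(mts),
                             target=np.array([side] * n))

    def test_eleven_trials_split_five_six_with_median_to_long(self):
        mts = np.linspace(0.1, 0.5, 11)
        g = P.group_trials(self._events(mts))
        assert len(g[("left", "brief")]) == 5
        assert len(g[("left", "long")]) == 6
        median_trial = 5
        assert median_trial in g[("left", "long")]

    def test_constant_rate_roi_has_flat_peth(self):
        rng = np.random.default_rng(0)
        data = rng.poisson(2.0, size=(20, 1, 80)).astype(float)
        binned = P.BinnedPopulation(data=data, window_ms=(-100, 700),
                                    lock_event="lift")
        ev = self._events(np.linspace(0.1, 0.4, 20))
        peths = P.group_and_peth(binned, ev)
        for trace in peths.values():
            assert abs(trace.mean() - 2.0) < 0.3
            assert trace.std() < 0.6

    def test_peth_peak_matches_planted_transient_latency(self):
        latency_bin = 30
        data = np.zeros((30, 1, 80))
        data[:, 0, latency_bin] = 5.0
        binned = P.BinnedPopulation(data=data, window_ms=(-100, 700),
                                    lock_event="lift")
        ev = self._events(np.linspace(0.1, 0.4, 30))
        peths = P.group_and_peth(binned, ev, smoothing_sd_ms=35.0)
        for trace in peths.values():
            assert abs(int(np.argmax(trace[0])) - latency_bin) <= 1

    def test_empty_group_omitted_with_warning(self):
        ev = self._events([0.2, 0.3, 0.25], side="left")
        data = np.ones((3, 1, 10))
        binned = P.BinnedPopulation(data=data, window_ms=(0, 100),
                                    lock_event="cue")
        peths = P.group_and_peth(binned, ev)
        assert ("right", "brief") not in peths


class TestKinematicLocking:
    def test_linear_interpolation_onto_bin_centers(self):
        t = np.arange(0.0, 1.0, 1 / 150.0)
        a = np.tile((10.0 * t)[None, :, None], (2, 1, 3))
        out = P.bin_kinematics(a, t, np.array([0.5, 0.5]), (-100.0, 100.0),
                               smoothing_sd_ms=0.0)
        centers = 0.5 + (-0.1 + 0.01 * (0.5 + np.arange(20)))
        assert out.shape == (2, 20, 3)
        assert np.allclose(out[0, :, 0], 10.0 * centers, atol=1e-9)
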