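import math

import numpy as np
import pytest
from scipy import stats

import planotaxis as pt
from planotaxis import analytics


def make_traj(xs, ys):
    n = len(xs)
    return pt.Trajectory(
        t=np.arange(n, dtype=float),
        x=np.asarray(xs, dtype=float),
        y=np.asarray(ys, dtype=float),
        phi=np.zeros(n),
    )


class TestCircularSummary:
    def test_identical_bearings_infinite_precision(self):
        s = pt.circular_summary([37.0] * 5)
        assert s.resultant_length == pytest.approx(1.0)
        assert math.isinf(s.precision_index)

    def test_perfect_cancellation(self):
        s = pt.circular_summary([0.0, 90.0, 180.0, 270.0])
        assert s.resultant_length == pytest.approx(0.0, abs=1e-12)
        assert s.precision_index == 0.0

    def test_hand_computed_two_bearing_case(self):
        s = pt.circular_summary([0.0, 90.0])
        assert s.resultant_length == pytest.approx(math.sqrt(0.5), abs=1e-12)
        assert s.precision_index == pytest.approx(1.2011, abs=1e-4)
        assert s.mean_bearing == pytest.approx(45.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pt.circular_summary([])

    def test_circular_sd_matches_scipy(self, rng):
        bearings = rng.normal(90.0, 25.0, size=500)
        s = pt.circular_summary(bearings)
        expected = stats.circstd(np.radians(bearings))
        assert s.circular_sd == pytest.approx(expected, rel=1e-9)

    def test_precision_decreases_with_noise(self, rng):
        precisions = []
        for noise_sd in (5.0, 15.0, 30.0, 60.0):
            bearings = rng.normal(180.0, noise_sd, size=2000)
            precisions.append(pt.circular_summary(bearings).precision_index)
        assert all(a > b for a, b in zip(precisions, precisions[1:]))


class TestEscapeValue:
    def test_straight_away_scores_one(self):
        src = pt.LightSource(propagation_bearing=0.0)  # rays travel +y
        tr = make_traj([0, 0, 0], [0, 1, 2])
        assert pt.escape_value(tr, src) == pytest.approx(1.0)

    def test_straight_toward_scores_minus_one(self):
        src = pt.LightSource(propagation_bearing=0.0)
        tr = make_traj([0, 0, 0], [0, -1, -2])
        assert pt.escape_value(tr, src) == pytest.approx(-1.0)

    def test_perpendicular_scores_zero(self):
        src = pt.LightSource(propagation_bearing=0.0)
        tr = make_traj([0, 1, 2], [0, 0, 0])
        assert pt.escape_value(tr, src) == pytest.approx(0.0)

    def test_single_point_rejected(self):
        src = pt.LightSource()
        with pytest.raises(ValueError):
            pt.escape_value(make_traj([0.0], [0.0]), src)

    @pytest.mark.parametrize("rotation", [30.0, 145.0, 270.0])
    def test_invariant_under_joint_rotation(self, rotation, rng):
        steps = rng.normal(size=(20, 2))
        pos = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        tr = make_traj(pos[:, 0], pos[:, 1])
        src = pt.LightSource(propagation_bearing=10.0)
        base = pt.escape_value(tr, src)
        # rotate bearings clockwise by `rotation`: (sin b, cos b) -> (sin(b+r), cos(b+r))
        a = math.radians(rotation)
        rot = np.array([[math.cos(a), math.sin(a)], [-math.sin(a), math.cos(a)]])
        rotated = pos @ rot.T
        tr_rot = make_traj(rotated[:, 0], rotated[:, 1])
        src_rot = pt.LightSource(propagation_bearing=10.0 + rotation)
        assert pt.escape_value(tr_rot, src_rot) == pytest.approx(base, abs=1e-9)


class TestTwinTail:
    @pytest.mark.parametrize(
        "bearings, left, right, sep",
        [
            ([170, 170, 190, 190], 170.0, 190.0, 20.0),
            ([150, 160, 170, 190, 200, 210], 160.0, 200.0, 40.0),
        ],
    )
    def test_median_separation(self, bearings, left, right, sep):
        res = pt.twin_tail_separation(bearings)
        assert res.left_median == pytest.approx(left)
        assert res.right_median == pytest.approx(right)
        assert res.separation == pytest.approx(sep)

    def test_empty_group_signals(self):
        with pytest.raises(ValueError):
            pt.twin_tail_separation([10.0, 20.0, 170.0])

    def test_mirror_symmetric_sample(self, rng):
        """On a mirror-symmetrized sample the separation is twice the
        one-sided median deviation from straight-away."""
        left = 180.0 - np.abs(rng.normal(25.0, 5.0, size=51))
        sample = np.concatenate([left, 360.0 - left])
        res = pt.twin_tail_separation(sample)
        one_sided = np.median(180.0 - left)
        assert res.separation == pytest.approx(2 * one_sided, abs=1e-9)


class TestRoseHistogram:
    def test_all_away(self):
        pct = pt.rose_histogram([180.0] * 7)
        assert pct[2] == 100.0 and pct.sum() == pytest.approx(100.0)

    def test_uniform_grid_splits_evenly(self):
        pct = pt.rose_histogram(np.arange(0.0, 360.0, 1.0))
        assert np.allclose(pct, 25.0)

    def test_toward_quadrant_wraps_through_zero(self):
        pct = pt.rose_histogram([10.0, 350.0])
        assert pct[0] == 100.0

    def test_rotation_permutes_bins(self, rng):
        bearings = rng.uniform(0.0, 360.0, size=200)
        base = pt.rose_histogram(bearings)
        rotated = pt.rose_histogram(bearings + 90.0)
        assert np.allclose(np.roll(base, 1), rotated)


class TestTurnLightRegression:
    def test_perfectly_linear(self):
        light = np.linspace(-170, 170, 30)
        turn = -0.5 * light
        r2_all, r2_below = pt.turn_light_regression(light, turn)
        assert r2_all == pytest.approx(1.0)
        assert r2_below == pytest.approx(1.0)

    def test_null_noise_has_no_correlation(self, rng):
        light = rng.uniform(-180, 180, size=1000)
        turn = rng.uniform(-180, 180, size=1000)
        r2_all, r2_below = pt.turn_light_regression(light, turn)
        assert r2_all < 0.02
        assert r2_below < 0.03

    def test_model_scatter_shows_band_contrast(self):
        params = pt.TrackingFixtureParams(seed=2)
        data = pt.generate_turn_dataset(params, 1000)
        r2_all, r2_below = pt.turn_light_regression(
            data["light_angle_deg"], data["turn_angle_deg"]
        )
        assert r2_below > r2_all
        assert r2_below > 0.3

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pt.turn_light_regression([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pt.turn_light_regression([5.0] * 10, list(range(10)))


class TestExtractWigwag:
    def test_constant_heading_no_events(self):
        angles, intervals = pt.extract_wigwag(np.arange(10.0), np.full(10, 45.0))
        assert angles.size == 0 and intervals.size == 0

    def test_monotone_heading_no_events(self):
        angles, _ = pt.extract_wigwag(np.arange(10.0), np.arange(10.0) * 5.0)
        assert angles.size == 0

    def test_sawtooth_reversals(self):
        # heading alternates +10/-10 every second: 20-degree swings
        t = np.arange(8.0)
        phi = np.where(np.arange(8) % 2 == 0, 10.0, -10.0)
        angles, intervals = pt.extract_wigwag(t, phi)
        assert np.allclose(np.abs(angles), 20.0)
        assert np.allclose(intervals, 1.0)

    def test_deadband_suppresses_jitter(self, rng):
        t = np.arange(200.0)
        phi = np.full(200, 90.0) + rng.normal(0.0, 0.1, size=200)
        angles, _ = pt.extract_wigwag(t, phi, deadband_deg=1.0)
        assert angles.size == 0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            pt.extract_wigwag([0.0, 1.0], [0.0, 1.0])


class TestWigwagFits:
    def test_two_point_normal_mle(self):
        fit = pt.fit_wigwag_distributions([-10.0, 10.0], [1.0, 1.0])
        assert fit.normal_mean_mle == pytest.approx(0.0)
        assert fit.normal_sd_mle == pytest.approx(10.0)  # 1/n MLE variance
        assert fit.lognormal_mu_mle == pytest.approx(0.0)
        assert fit.lognormal_sigma_mle == pytest.approx(0.0)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            pt.fit_wigwag_distributions([1.0, 2.0], [0.5, -0.1])

    def test_parameter_recovery_roundtrip(self, rng):
        n = 10_000
        angles = rng.normal(0.0, 18.7, size=n)
        intervals = rng.lognormal(-0.15, 0.44, size=n)
        fit = pt.fit_wigwag_distributions(angles, intervals)
        assert abs(fit.normal_sd_mle - 18.7) < 3 * 18.7 / math.sqrt(2 * n)
        assert abs(fit.normal_mean_mle) < 3 * 18.7 / math.sqrt(n)
        assert abs(fit.lognormal_mu_mle + 0.15) < 3 * 0.44 / math.sqrt(n)
        assert abs(fit.lognormal_sigma_mle - 0.44) < 3 * 0.44 / math.sqrt(2 * n)


class TestSummarizeCohort:
    def test_summary_row_fields(self):
        cfg = pt.SimulationConfig(seed=2)
        trajectories = pt.run_cohort(cfg, 15)
        row = analytics.summarize_cohort(trajectories, cfg.sources[0])
        assert row["n"] == 15
        assert 0.0 <= row["resultant_length"] <= 1.0
        assert -1.0 <= row["mean_escape"] <= 1.0
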