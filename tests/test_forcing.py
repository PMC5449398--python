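"""Activity thresholding, orbit segmentation and prediction scoring."""

import numpy as np
import pytest

from havok import (
    ActivityConfig,
    HavokModel,
    Orbit,
    PredictionReport,
    detect_activity,
    evaluate_prediction,
    forcing_stats,
    segment_orbits,
    shuffle_control,
)


class TestDetectActivity:
    def test_zero_signal_all_inactive(self):
        assert not detect_activity(np.zeros(100), ActivityConfig(0.002)).any()

    def test_threshold_is_strict(self):
        v = np.full(50, 0.002)
        assert not detect_activity(v, ActivityConfig(0.002)).any()
        assert detect_activity(v * 1.001, ActivityConfig(0.002)).all()

    def test_sign_is_irrelevant(self):
        v = np.array([-0.01, 0.0, 0.01])
        np.testing.assert_array_equal(
            detect_activity(v, ActivityConfig(0.002)), [True, False, True]
        )

    def test_smoothing_suppresses_single_spikes(self):
        v = np.zeros(101)
        v[50] = 0.01
        cfg = ActivityConfig(threshold=0.002, smoothing_window=11)
        assert detect_activity(v, ActivityConfig(0.002))[50]
        assert not detect_activity(v, cfg)[50]  # 0.01/11 < 0.002


class TestSegmentOrbits:
    def test_sine_has_four_switches_over_two_periods(self):
        t = np.arange(0, 4 * np.pi + 0.05, 0.01)
        orbits, switch_times = segment_orbits(np.sin(t), dt=0.01)
        assert len(switch_times) == 4
        np.testing.assert_allclose(
            switch_times, [np.pi, 2 * np.pi, 3 * np.pi, 4 * np.pi], atol=0.01
        )
        assert sum(o.switching for o in orbits) == 4

    def test_strictly_positive_signal_has_no_switches(self):
        t = np.arange(0, 20, 0.01)
        orbits, switch_times = segment_orbits(2.0 + np.sin(t), dt=0.01)
        assert len(switch_times) == 0
        assert all(not o.switching for o in orbits)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            segment_orbits(np.ones(100), dt=0.01)

    def test_monotone_signal_rejected(self):
        with pytest.raises(ValueError, match="extrema"):
            segment_orbits(np.arange(100.0), dt=0.01)

    def test_orbits_are_contiguous_and_ordered(self, lorenz_series):
        x = lorenz_series.window(200.0, 220.0).values
        orbits, switch_times = segment_orbits(x, dt=0.001, t0=200.0)
        for a, b in zip(orbits, orbits[1:]):
            assert a.end == b.start
        assert sum(o.switching for o in orbits) == len(switch_times)
        # switch times interpolate actual sign changes
        assert all(200.0 < t < 220.0 for t in switch_times)


def _toy_orbits():
    """Three quiet orbits, then a switching orbit ending at t = 4.0."""
    orbits = [
        Orbit(start=0, end=100, switching=False),
        Orbit(start=100, end=200, switching=False),
        Orbit(start=200, end=300, switching=False),
        Orbit(start=300, end=400, switching=True, switch_time=4.0),
    ]
    return orbits, 0.01  # dt


class TestEvaluatePrediction:
    def test_all_true_mask_orbit_mode(self):
        orbits, dt = _toy_orbits()
        rep = evaluate_prediction(orbits, np.ones(401, bool), dt, mode="orbit")
        assert rep.detection_rate == 1.0
        assert rep.false_positive_rate == 1.0

    def test_all_false_mask(self):
        orbits, dt = _toy_orbits()
        for mode in ("orbit", "event"):
            rep = evaluate_prediction(orbits, np.zeros(401, bool), dt, mode=mode)
            assert rep.detection_rate == 0.0
            assert rep.false_positive_rate == 0.0
            assert rep.lead_times == []

    def test_event_mode_attributes_warning_burst(self):
        """A burst shortly before the switch detects it, and the quiet
        orbits it touches are not false positives."""
        orbits, dt = _toy_orbits()
        mask = np.zeros(401, bool)
        mask[250:320] = True  # burst from t=2.5 to t=3.2, switch at 4.0
        rep = evaluate_prediction(orbits, mask, dt, mode="event", pre_horizon=1.5)
        assert rep.n_detected == 1
        assert rep.n_false_positive == 0
        assert rep.lead_times[0] == pytest.approx(4.0 - 2.5)

    def test_event_mode_flags_isolated_burst(self):
        orbits, dt = _toy_orbits()
        mask = np.zeros(401, bool)
        mask[50:60] = True  # t=0.5: no switch within pre_horizon=1.5
        rep = evaluate_prediction(orbits, mask, dt, mode="event", pre_horizon=1.5)
        assert rep.n_detected == 0
        assert rep.n_false_positive == 1

    def test_event_mode_excuses_post_switch_residue(self):
        orbits = [
            Orbit(start=0, end=100, switching=True, switch_time=0.5),
            Orbit(start=100, end=300, switching=False),
            Orbit(start=300, end=400, switching=False),
        ]
        mask = np.zeros(401, bool)
        mask[40:90] = True  # covers the switch and trails into t in (0.5, 0.9)
        rep = evaluate_prediction(orbits, mask, 0.01, mode="event", post_horizon=0.5)
        assert rep.n_detected == 1
        assert rep.n_false_positive == 0

    def test_orbit_mode_counts_every_active_quiet_orbit(self):
        orbits, dt = _toy_orbits()
        mask = np.zeros(401, bool)
        mask[250:320] = True
        rep = evaluate_prediction(orbits, mask, dt, mode="orbit")
        # the early-warning burst touching quiet orbit 3 counts against it
        assert rep.n_false_positive == 1
        assert rep.n_detected == 1

    def test_empty_orbit_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_prediction([], np.zeros(10, bool), 0.01)

    def test_rates_monotone_in_threshold(self, lorenz_series, lorenz_embedding):
        """Sweeping the threshold traces an ROC: both rates nonincreasing."""
        from havok import project_coordinates

        seg = lorenz_series.window(200.0, 240.0)
        times, coords = project_coordinates(seg, lorenz_embedding)
        v_r = coords[:, 10]
        orbits, _ = segment_orbits(seg.values[99:], seg.dt, t0=times[0])
        det, fpr = [], []
        for thr in np.geomspace(1e-4, 1e-2, 8):
            mask = detect_activity(v_r, ActivityConfig(thr))
            rep = evaluate_prediction(orbits, mask, seg.dt, t0=times[0], mode="orbit")
            det.append(rep.detection_rate)
            fpr.append(rep.false_positive_rate)
        assert np.all(np.diff(det) <= 1e-12)
        assert np.all(np.diff(fpr) <= 1e-12)


class TestReport:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PredictionReport(
                n_switch_events=2, n_detected=3, n_nonswitch_orbits=0, n_false_positive=0
            )

    def test_roundtrip(self, tmp_path):
        rep = PredictionReport(
            n_switch_events=10,
            n_detected=9,
            n_nonswitch_orbits=40,
            n_false_positive=2,
            lead_times=[0.5, 1.25, 0.875],
        )
        rep.save(tmp_path / "rep.json")
        back = PredictionReport.load(tmp_path / "rep.json")
        assert back == rep

    def test_empty_report_roundtrip(self, tmp_path):
        rep = PredictionReport(0, 0, 0, 0)
        rep.save(tmp_path / "rep.json")
        back = PredictionReport.load(tmp_path / "rep.json")
        assert back.n_switch_events == 0 and back.lead_times == []


class TestForcingStats:
    def test_gaussian_sample_has_no_excess_kurtosis(self):
        v = np.random.default_rng(0).standard_normal(100_000)
        assert abs(forcing_stats(v).excess_kurtosis) < 0.1

    def test_histogram_integrates_to_one(self, rng):
        stats = forcing_stats(rng.laplace(size=5000))
        integral = np.sum(stats.density * np.diff(stats.bin_edges))
        assert integral == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            forcing_stats(np.full(200, 1.5))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="100 samples"):
            forcing_stats(np.arange(50.0))


@pytest.fixture()
def toy_model():
    A = np.array([[0.0, 2.0], [-2.0, -0.05]])
    return HavokModel(A=A, B=np.array([1.0, 0.3]), r=3, dt=0.01)


class TestShuffleControl:

    def test_identity_permutation_agrees_fully(self, toy_model, rng):
        u = rng.standard_normal(2000) * (rng.random(2000) < 0.05)
        out = shuffle_control(
            toy_model, u, v0=[1.0, 0.0], seed=0, permutation=np.arange(2000)
        )
        assert out["timing_agreement"] == 1.0
        assert out["baseline_switch_count"] == out["shuffled_switch_count"]

    def test_shuffle_preserves_histogram(self, toy_model, rng):
        u = rng.standard_normal(500)
        rng2 = np.random.default_rng(3)
        shuffled = rng2.permutation(u)
        assert np.array_equal(np.sort(shuffled), np.sort(u))
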