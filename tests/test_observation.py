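import numpy as np
import pandas as pd
import pytest

from fishssm.errors import ConfigurationError
from fishssm.movement import MovementParams, simulate_track
from fishssm.observation import (
    DetectionParams,
    ReceiverArray,
    bin_detections,
    classify_day_night,
    detection_probability,
    simulate_detections,
)


class TestDetectionProbability:
    def test_half_at_inflection_point(self):
        params = DetectionParams(d50=150.0, slope=-0.02)
        assert detection_probability(150.0, params) == pytest.approx(0.5)

    def test_direct_evaluation_inside_range(self):
        params = DetectionParams(d50=150.0, slope=-0.02)
        # slope*(100-150) = 1 -> expit(1)
        assert detection_probability(100.0, params) == pytest.approx(0.7310586, abs=1e-6)

    def test_vanishes_at_large_distance(self):
        params = DetectionParams(d50=150.0, slope=-0.02)
        assert detection_probability(5000.0, params) < 1e-10

    def test_monotone_decreasing_into_unit_interval(self):
        params = DetectionParams(d50=150.0, slope=-0.015)
        d = np.linspace(0, 2000, 200)
        p = detection_probability(d, params)
        assert np.all(np.diff(p) < 0)
        assert np.all((p > 0) & (p < 1))

    def test_negative_distance_rejected(self):
        params = DetectionParams(d50=150.0, slope=-0.02)
        with pytest.raises(ValueError):
            detection_probability(-1.0, params)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(d50=150.0, slope=0.02)


class TestSimulateDetections:
    def _track(self, n=200):
        params = MovementParams(0.0, 0.0, 0.001, 100.0)
        return simulate_track(params, [1] * n, (0.0, 0.0), seed=1)

    def test_certain_detection_gives_full_counts(self, receiver_grid_14):
        params = DetectionParams(d50=1e6, slope=-0.02)  # probability ~ 1
        series = simulate_detections(self._track(), receiver_grid_14, params, seed=2)
        assert np.all(series.counts == 6)

    def test_impossible_detection_gives_zero_counts(self, receiver_grid_14):
        params = DetectionParams(d50=-1e6, slope=-5.0)  # probability ~ 0
        series = simulate_detections(self._track(), receiver_grid_14, params, seed=3)
        assert np.all(series.counts == 0)

    def test_counts_bounded_by_emissions(self, receiver_grid_14):
        params = DetectionParams(d50=150.0, slope=-0.02, emissions_per_step=6)
        series = simulate_detections(self._track(), receiver_grid_14, params, seed=4)
        assert series.counts.min() >= 0 and series.counts.max() <= 6

    def test_mean_count_matches_binomial_mean(self):
        receivers = ReceiverArray(ids=("a", "b"), coords=[[50.0, 0.0], [300.0, 0.0]])
        params = DetectionParams(d50=150.0, slope=-0.02)
        # frozen fish: fixed geometry, many steps
        track = simulate_track(
            MovementParams(0.0, 0.0, 0.001, 100.0), [2] * 10_000, (0.0, 0.0), seed=0
        )
        series = simulate_detections(track, receivers, params, seed=5)
        d = np.array([50.0, 300.0])
        pd_ = detection_probability(d, params)
        for j in range(2):
            mean = series.counts[:, j].mean()
            se = np.sqrt(6 * pd_[j] * (1 - pd_[j]) / 10_000)
            assert abs(mean - 6 * pd_[j]) < 3 * se


class TestBinDetections:
    def _receivers(self):
        return ReceiverArray(ids=("r1",), coords=[[0.0, 0.0]])

    def test_events_land_in_half_open_bins(self):
        origin = pd.Timestamp("2017-07-24T00:00:00Z")
        events = pd.DataFrame(
            {
                "timestamp": [origin, origin + pd.Timedelta(seconds=300), origin + pd.Timedelta(seconds=800)],
                "receiver_id": ["r1"] * 3,
            }
        )
        series = bin_detections(events, self._receivers(), 720.0, origin)
        assert series.counts[:, 0].tolist() == [2, 1]

    def test_empty_log_gives_zero_series(self):
        series = bin_detections(
            pd.DataFrame({"timestamp": [], "receiver_id": []}),
            self._receivers(),
            720.0,
            pd.Timestamp("2017-07-24T00:00:00Z"),
            n_steps=5,
        )
        assert series.counts.shape == (5, 1)
        assert series.counts.sum() == 0

    def test_total_count_conserved(self):
        # 10,764 events scattered over 10 days reappear exactly once each
        rng = np.random.default_rng(8)
        origin = pd.Timestamp("2017-07-24T00:00:00Z")
        offsets = rng.uniform(0, 10 * 86400, size=10_764)
        events = pd.DataFrame(
            {
                "timestamp": origin + pd.to_timedelta(offsets, unit="s"),
                "receiver_id": ["r1"] * 10_764,
            }
        )
        series = bin_detections(events, self._receivers(), 720.0, origin)
        assert series.counts.sum() == 10_764

    def test_event_before_origin_rejected(self):
        origin = pd.Timestamp("2017-07-24T00:00:00Z")
        events = pd.DataFrame(
            {"timestamp": [origin - pd.Timedelta(seconds=1)], "receiver_id": ["r1"]}
        )
        with pytest.raises(ValueError):
            bin_detections(events, self._receivers(), 720.0, origin)


class TestClassifyDayNight:
    def _table(self):
        return {
            "2017-07-24": ("2017-07-24T04:30:00Z", "2017-07-24T19:10:00Z"),
        }

    def test_second_before_sunrise_is_night(self):
        out = classify_day_night(["2017-07-24T04:29:59Z"], self._table())
        assert out.tolist() == [0]

    def test_sunrise_inclusive_sunset_exclusive(self):
        out = classify_day_night(
            ["2017-07-24T04:30:00Z", "2017-07-24T19:10:00Z"], self._table()
        )
        assert out.tolist() == [1, 0]

    def test_noon_is_day(self):
        assert classify_day_night(["2017-07-24T12:00:00Z"], self._table()).tolist() == [1]

    def test_uncovered_date_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_day_night(["2017-07-25T12:00:00Z"], self._table())
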