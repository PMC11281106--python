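"""Filtering chain, activity-threshold derivations, non-seated detection,
and window segmentation."""

import numpy as np
import pytest

from trunksway.ingest import NS_PER_S, SensorStream, UniformStream, resample_uniform
from trunksway import preprocess as pp


def uniform(values, rate=100.0, kind="accelerometer"):
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] == 1:
        values = values.T
    if values.shape[1] == 1:
        values = np.repeat(values, 3, axis=1)
    ts = (np.arange(values.shape[0]) * NS_PER_S / rate).astype(np.int64)
    return UniformStream(kind, ts, ("x", "y", "z"), values, rate, rate_hz=rate)


def sinusoid(freq, rate=100.0, seconds=20.0):
    t = np.arange(int(seconds * rate)) / rate
    return np.sin(2 * np.pi * freq * t)


class TestLowpass:
    def test_constant_unchanged(self):
        s = uniform(np.full(2000, 3.3))
        out = pp.lowpass_acc(s, 10.0)
        np.testing.assert_allclose(out.values, 3.3, atol=1e-9)

    def test_stopband_attenuation_40hz(self):
        x = sinusoid(40.0)
        out = pp.lowpass_acc(uniform(x), 10.0)
        assert np.sqrt(np.mean(out.values[:, 0] ** 2)) < 0.05 * np.sqrt(np.mean(x**2))

    def test_passband_1hz_preserved(self):
        x = sinusoid(1.0)
        out = pp.lowpass_acc(uniform(x), 10.0)
        core = slice(200, -200)  # ignore filter edge transients
        rms_ratio = np.sqrt(np.mean(out.values[core, 0] ** 2) / np.mean(x[core] ** 2))
        assert abs(rms_ratio - 1.0) < 0.02

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pp.lowpass_acc(uniform(np.zeros(100)), 60.0)


class TestGravityRemoval:
    def test_static_gravity_removed(self):
        vals = np.tile([0.0, 0.0, 9.81], (6000, 1))
        out = pp.remove_gravity(uniform(vals))
        burn = slice(500, -500)
        assert np.abs(out.values[burn]).max() < 0.05

    def test_zero_input_zero_output(self):
        out = pp.remove_gravity(uniform(np.zeros((1000, 3))))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_oscillation_on_gravity_preserved(self):
        x = sinusoid(5.0, seconds=60.0)
        vals = np.column_stack([x, x, 9.81 + x])
        out = pp.remove_gravity(uniform(vals))
        core = slice(1000, -1000)
        ratio = np.sqrt(np.mean(out.values[core, 2] ** 2) / np.mean(x[core] ** 2))
        assert abs(ratio - 1.0) < 0.05


class TestDetrendAndSmooth:
    def test_detrend_examples(self):
        np.testing.assert_allclose(pp.detrend_mean([1, 2, 3]), [-1, 0, 1])
        np.testing.assert_allclose(pp.detrend_mean(np.full(5, 7.0)), 0.0)
        x = np.array([-1.0, 0.0, 1.0])
        np.testing.assert_allclose(pp.detrend_mean(x), x)
        assert abs(pp.detrend_mean(np.random.default_rng(0).normal(3, 1, 100)).mean()) < 1e-12

    def test_moving_average_constant(self):
        np.testing.assert_allclose(pp.moving_average(np.full(20, 2.5), 7), 2.5)

    def test_moving_average_impulse(self):
        x = np.zeros(11)
        x[5] = 1.0
        out = pp.moving_average(x, 5)
        np.testing.assert_allclose(out[3:8], 0.2)
        np.testing.assert_allclose(out[[0, 1, 9, 10]], 0.0)

    def test_moving_average_interior_means(self):
        out = pp.moving_average(np.array([0.0, 3, 0, 3, 0]), 3)
        np.testing.assert_allclose(out[1:4], [1, 2, 1])

    def test_even_window_promoted_to_odd(self):
        x = np.arange(10.0)
        np.testing.assert_allclose(pp.moving_average(x, 4), pp.moving_average(x, 5))

    def test_window_below_one_rejected(self):
        with pytest.raises(ValueError):
            pp.moving_average(np.ones(5), 0)


class TestThresholds:
    def test_kinematic_magnitude(self):
        mag = pp.acceleration_magnitude(1.02, 1.15, 1.41)
        assert abs(mag - np.sqrt(1.02**2 + 1.15**2 + 1.41**2)) < 1e-12
        assert abs(mag - 2.0859) < 5e-4
        assert round(mag) == 2

    def test_magnitude_examples(self):
        assert pp.acceleration_magnitude(0, 0, 0) == 0
        assert pp.acceleration_magnitude(3, 4, 0) == 5

    def test_met_threshold(self):
        mag = pp.threshold_from_met(3.0)
        assert abs(mag - (3 + 8.5548) / 5.289) < 1e-12
        assert round(mag) == 2

    def test_met_inverse_identity(self):
        mag = pp.threshold_from_met(3.0)
        assert np.isclose(5.289 * mag - 8.5548, 3.0)
        assert pp.threshold_from_met(0.0, 1.0, 0.0) == 0.0

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            pp.threshold_from_met(3.0, slope=0.0)

    def test_both_derivations_round_to_same_integer(self):
        spec = pp.ThresholdSpec()
        assert round(spec.kinematic_magnitude()) == round(spec.met_magnitude()) == 2


class TestDetectNonseated:
    def test_all_below_threshold(self):
        assert pp.detect_nonseated(np.full(100, 0.5)) == []

    def test_single_run_no_guard(self):
        out = pp.detect_nonseated(np.array([0.5, 3.0, 3.0, 0.5]), guard_seconds=0.0)
        assert out == [(1, 3)]

    def test_guard_dilation_and_merge(self):
        mag = np.zeros(100)
        mag[10:12] = 3.0
        mag[15:17] = 3.0
        out = pp.detect_nonseated(mag, rate_hz=10.0, guard_seconds=0.5)
        assert out == [(5, 22)]  # two runs dilated by 5 samples merge

    def test_retained_samples_below_threshold(self, rng):
        mag = np.abs(rng.normal(1.0, 1.0, size=2000))
        intervals = pp.detect_nonseated(mag, threshold=2.0, guard_seconds=0.0)
        mask = pp.retained_mask(mag.size, intervals)
        assert np.all(mag[mask] <= 2.0)

    def test_recovers_injected_bouts_through_pipeline(self, bout_recording):
        acc = resample_uniform(bout_recording.streams["accelerometer"], 100.0)
        proc = pp.preprocess_accelerometer(acc)
        mag = pp.acceleration_magnitude(*proc.values.T)
        detected = pp.detect_nonseated(mag, 2.0, 100.0, 0.5)
        truth = bout_recording.walk_intervals
        assert len(detected) == len(truth) == 3
        for (ds, de), (ts, te) in zip(detected, truth):
            center = (ts + te) / 2
            assert ds <= center <= de


class TestSegmentWindows:
    def test_seven_window_labels(self):
        labels = [w.label for w in pp.segment_windows(7 * 9000, 100.0, 1.5)]
        assert labels == ["AM1", "AM2", "Lunch", "Lunch", "Lunch", "PM1", "PM2"]

    def test_nine_windows_symmetric(self):
        labels = [w.label for w in pp.segment_windows(9 * 9000, 100.0, 1.5)]
        assert labels.count("Lunch") == 3
        assert sum(l.startswith("AM") for l in labels) == 3
        assert sum(l.startswith("PM") for l in labels) == 3

    def test_even_count_tie_break(self):
        # center = floor(8/2) = 4 -> lunch windows 3..5
        labels = [w.label for w in pp.segment_windows(8 * 9000, 100.0, 1.5)]
        assert labels == ["AM1", "AM2", "AM3", "Lunch", "Lunch", "Lunch", "PM1", "PM2"]

    def test_windows_tile_without_overlap(self):
        wins = pp.segment_windows(7 * 9000 + 123, 100.0, 1.5)
        for a, b in zip(wins[:-1], wins[1:]):
            assert a.end_index == b.start_index
        assert wins[0].start_index == 0
        assert wins[-1].end_index == 7 * 9000  # trailing partial discarded

    def test_too_short_session(self):
        with pytest.raises(pp.SessionTooShortError):
            pp.segment_windows(2 * 9000, 100.0, 1.5)


def test_pipeline_order_matters():
    """Guard: the documented order (lowpass -> gravity -> detrend -> smooth)
    is not interchangeable with, e.g., gravity removal before lowpass plus
    smoothing before detrending on a transient-rich signal."""
    rng = np.random.default_rng(7)
    t = np.arange(4000) / 100.0
    x = 9.81 + 2 * np.sin(2 * np.pi * 0.2 * t) + rng.normal(0, 0.5, t.size)
    x[1000:1100] += 8.0
    s = uniform(np.column_stack([x, x, x]))
    canonical = pp.preprocess_accelerometer(s).values
    permuted = pp.lowpass_acc(pp.remove_gravity(s))
    permuted = permuted.with_values(
        pp.detrend_mean(pp.moving_average(permuted.values, 150))
    )
    assert not np.allclose(canonical, permuted.values, atol=1e-6)
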