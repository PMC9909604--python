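import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sumus import (
    GeneratorConfig,
    ImuTrace,
    OnsetNotFoundError,
    detect_onset,
    gen_rhythmic_trace,
    summarize_series,
    trim_window,
    vector_magnitude,
)
from sumus.kinematics import ScalarSeries

from conftest import RATE, make_burst_series


def _trace_from_acc(acc, rate=20.0):
    t = np.arange(len(acc)) / rate
    return ImuTrace("s", 1, t=t, user_acc=np.asarray(acc, dtype=float),
                    nominal_rate=rate)


class TestVectorMagnitude:
    def test_345_triangle(self):
        series = vector_magnitude(_trace_from_acc([[3.0, 4.0, 0.0]]))
        assert series.values[0] == pytest.approx(5.0)
        assert series.units == "m/s^2"

    def test_zero_vector(self):
        assert vector_magnitude(_trace_from_acc([[0.0, 0.0, 0.0]])).values[0] == 0.0

    def test_rotation_invariance_random_rotations(self):
        """The magnitude must not depend on how the watch sits on the wrist:
        re-orienting every vector by a fixed rotation leaves it unchanged."""
        rng = np.random.default_rng(5)
        acc = rng.normal(size=(400, 3))
        base = vector_magnitude(_trace_from_acc(acc)).values
        for _ in range(5):
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            rotated = vector_magnitude(_trace_from_acc(acc @ q.T)).values
            np.testing.assert_allclose(rotated, base, atol=1e-9)

    def test_absent_channel_raises(self):
        with pytest.raises(ValueError, match="rotation_rate"):
            vector_magnitude(_trace_from_acc([[1, 1, 1]]), "rotation_rate")

    def test_nan_samples_are_dropped(self):
        acc = np.ones((10, 3))
        acc[4, 1] = np.nan
        series = vector_magnitude(_trace_from_acc(acc))
        assert len(series) == 9


class TestDetectOnset:
    def test_quiet_baseline_then_bursts(self):
        """10 s of noise before rhythmic bursts: onset lands within half a
        second of the first movement."""
        series = make_burst_series(start_s=10.0, seed=1)
        onset = detect_onset(series, baseline_window=5.0, k=3.0, sustain=1.0)
        assert 9.5 <= onset <= 10.5

    def test_movement_from_start_returns_zero(self):
        series = make_burst_series(start_s=0.0, seed=2)
        assert detect_onset(series, baseline_window=5.0, k=3.0, sustain=1.0) == 0.0

    def test_pure_noise_never_meets_criterion(self):
        rng = np.random.default_rng(3)
        series = ScalarSeries(np.arange(1200) / RATE,
                              np.abs(rng.normal(0, 0.05, 1200)), "m/s^2", RATE)
        with pytest.raises(OnsetNotFoundError):
            detect_onset(series, baseline_window=5.0, k=10.0, sustain=2.0)

    def test_too_short_series_rejected(self):
        series = make_burst_series(start_s=0.0, duration_s=6.0)
        with pytest.raises(ValueError):
            detect_onset(series, baseline_window=5.0, k=3.0, sustain=2.0)


class TestTrimWindow:
    def test_12min_trace_gives_10000_samples(self):
        trace = gen_rhythmic_trace(GeneratorConfig(seed=4, duration=720.0))
        acc = vector_magnitude(trace)
        rot = vector_magnitude(trace, "rotation_rate")
        window = trim_window(acc, rot, onset=5.0)
        assert len(window.acc) == 10_000
        assert len(window.rot) == 10_000
        assert window.acc.t[0] == pytest.approx(5.0)

    def test_trim_is_idempotent_on_exact_window(self):
        trace = gen_rhythmic_trace(GeneratorConfig(seed=4, duration=500.0))
        acc = vector_magnitude(trace)
        window = trim_window(acc, None, onset=0.0)
        again = trim_window(window.acc, None, onset=0.0)
        np.testing.assert_array_equal(window.acc.values, again.acc.values)
        np.testing.assert_array_equal(window.acc.t, again.acc.t)

    def test_insufficient_data_reports_available_duration(self):
        trace = gen_rhythmic_trace(GeneratorConfig(seed=4, duration=400.0))
        acc = vector_magnitude(trace)
        with pytest.raises(ValueError, match="400"):
            trim_window(acc, None, onset=0.0)


class TestSummarize:
    def test_constant_series(self):
        series = ScalarSeries(np.arange(5) / RATE, np.full(5, 3.0), "m/s^2", RATE)
        s = summarize_series(series)
        assert (s.mean, s.sd, s.cv, s.max, s.min) == (3.0, 0.0, 0.0, 3.0, 3.0)

    def test_one_two_three(self):
        series = ScalarSeries(np.arange(3) / RATE, np.array([1.0, 2.0, 3.0]),
                              "m/s^2", RATE)
        s = summarize_series(series)
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)  # sample SD, n-1 denominator
        assert s.cv == pytest.approx(0.5)

    def test_near_zero_mean_gives_nan_cv_with_warning(self):
        series = ScalarSeries(np.arange(3) / RATE, np.zeros(3), "m/s^2", RATE)
        with pytest.warns(RuntimeWarning):
            s = summarize_series(series)
        assert np.isnan(s.cv)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.floats(0.01, 100.0))
    def test_cv_is_scale_invariant_and_matches_two_pass_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0.1, 5.0, 50)
        t = np.arange(50) / RATE
        s = summarize_series(ScalarSeries(t, v, "m/s^2", RATE))
        sk = summarize_series(ScalarSeries(t, k * v, "m/s^2", RATE))
        assert sk.cv == pytest.approx(s.cv, rel=1e-9)
        # brute-force two-pass oracle
        mean = sum(v) / len(v)
        sd = (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5
        assert s.mean == pytest.approx(mean, abs=1e-12)
        assert s.sd == pytest.approx(sd, abs=1e-12)
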