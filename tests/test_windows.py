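"""Stream alignment and sliding-window dataset construction."""

import numpy as np
import pytest

import gaitcount as gc


def _mag(n, rate=30.0):
    rng = np.random.default_rng(n)
    return gc.ScalarTrace(t=gc.regular_time_ms(n, rate), v=rng.normal(9.81, 1, n), kind="magnitude")


def _rec(duration=60, seed=0, freq=2.0):
    return gc.generate_walk(gc.GaitScenario(duration_s=duration, seed=seed, step_freq_hz=freq))


class TestAlignStreams:
    def test_identical_timestamps_unchanged(self):
        rec = _rec(10)
        a, p = gc.align_streams(rec.accel, rec.pressure)
        np.testing.assert_array_equal(a.t, rec.accel.t)
        np.testing.assert_array_equal(p.v, rec.pressure.v)
        assert len(a) == len(p)

    def test_small_shift_within_tolerance(self):
        rec = _rec(10)
        shifted = gc.ScalarTrace(t=rec.pressure.t + 10, v=rec.pressure.v, kind="pressure")
        a, p = gc.align_streams(rec.accel, shifted)
        assert len(a) == len(p) > 0.9 * len(rec.accel)

    def test_large_skew_pairs_dropped(self):
        t = gc.regular_time_ms(10, 30.0)
        accel = gc.AccelTrace(t=t, x=np.zeros(10), y=np.zeros(10), z=np.ones(10))
        # pressure sampled far more sparsely: most pairs exceed 50 ms skew
        pressure = gc.ScalarTrace(t=np.array([0, 300]), v=np.array([1.0, 2.0]), kind="pressure")
        a, p = gc.align_streams(accel, pressure)
        assert len(a) < 10

    def test_disjoint_spans_error(self):
        rec = _rec(5)
        later = gc.ScalarTrace(t=rec.pressure.t + 10_000_000, v=rec.pressure.v, kind="pressure")
        with pytest.raises(gc.AlignmentError):
            gc.align_streams(rec.accel, later)


class TestMakeWindows:
    def test_exactly_one_window_at_minimum_length(self):
        ds = gc.make_windows(_mag(60), gc.StepEvents(times=[]), "handheld")
        assert len(ds) == 1
        assert ds.features.shape == (1, 60)

    def test_two_windows_share_thirty_samples(self):
        mag = _mag(90)
        ds = gc.make_windows(mag, gc.StepEvents(times=[]), "pocket")
        assert len(ds) == 2
        np.testing.assert_array_equal(ds.features[0][30:], ds.features[1][:30])
        assert ds.window_starts[1] - ds.window_starts[0] == mag.t[30] - mag.t[0]

    @pytest.mark.parametrize("n", [60, 61, 90, 100, 1000, 333])
    def test_window_count_matches_bruteforce_start_enumeration(self, n):
        ds = gc.make_windows(_mag(n), gc.StepEvents(times=[]), "handbag")
        brute = sum(1 for s in range(0, n, 30) if s + 60 <= n and s % 30 == 0)
        assert len(ds) == brute == (n - 60) // 30 + 1

    def test_trace_shorter_than_window_rejected(self):
        with pytest.raises(gc.InsufficientDataError):
            gc.make_windows(_mag(59), gc.StepEvents(times=[]), "pocket")

    def test_labels_match_event_counts_per_window(self):
        rec = _rec(duration=30, seed=2)
        mag = gc.preprocess_accel(rec.accel)
        ds = gc.make_windows(mag, rec.truth, "handheld")
        for row in range(len(ds)):
            s = ds.window_starts[row]
            e = s + 2000
            assert ds.labels[row] == gc.count_events_in(rec.truth, s, e)

    def test_overlap_corrected_label_sum_approximates_total(self):
        rec = _rec(duration=120, seed=9, freq=1.8)
        mag = gc.preprocess_accel(rec.accel)
        ds = gc.make_windows(mag, rec.truth, "pocket")
        # each interior event is covered by exactly two windows at 50 % overlap
        estimated = ds.labels.sum() / 2.0
        max_per_window = ds.labels.max()
        assert abs(estimated - rec.truth.count) <= max_per_window

    def test_no_rng_in_windowing(self):
        mag = _mag(300)
        a = gc.make_windows(mag, gc.StepEvents(times=[1000, 2000]), "pocket")
        b = gc.make_windows(mag, gc.StepEvents(times=[1000, 2000]), "pocket")
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.window_starts, b.window_starts)


class TestWindowDataset:
    def test_roundtrip_through_frame(self, small_dataset):
        sub = small_dataset.subset(np.arange(25))
        back = gc.WindowDataset.from_frame(sub.to_frame())
        np.testing.assert_allclose(back.features, sub.features)
        np.testing.assert_array_equal(back.labels, sub.labels)
        np.testing.assert_array_equal(back.positions, sub.positions)

    def test_geometry_defaults(self, small_dataset):
        assert small_dataset.window_len == 60
        assert small_dataset.stride == 30

    def test_negative_labels_rejected(self):
        with pytest.raises(ValueError):
            gc.WindowDataset(
                features=np.zeros((1, 60)), labels=[-1], positions=["pocket"], window_starts=[0]
            )
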