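"""Gaussian encoding, peak decoding and the curve-correlation criterion."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitmark.encoding import (ConfidenceCurve, GaitEventSet, curve_correlation,
                               decode_peaks, encode_events)


def stream(times, side="L", etype="HS", source="truth"):
    return GaitEventSet.from_times(times, side, etype, source=source)


class TestEncode:
    def test_unit_peak_at_event_sample(self):
        curve = encode_events(stream([5000.0]), 10000, 1000.0)
        assert curve.values[5000] == 1.0

    def test_value_one_sigma_away(self):
        curve = encode_events(stream([5000.0]), 10000, 1000.0, sigma_ms=53.3)
        # sample closest to 5000 + 53.3 ms
        idx = 5053
        expected = np.exp(-((idx - 5000.0) ** 2) / (2 * 53.3**2))
        assert curve.values[idx] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(np.exp(-0.5), rel=1e-2)

    def test_zero_beyond_support(self):
        curve = encode_events(stream([5000.0]), 10000, 1000.0)
        assert curve.values[5300] == 0.0  # 300 ms away > 4 sigma
        assert curve.values[0] == 0.0

    def test_bounded_and_max_at_events(self):
        times = [1000.0, 3000.0, 5000.0]
        curve = encode_events(stream(times), 8000, 1000.0)
        assert curve.values.min() >= 0.0
        assert curve.values.max() <= 1.0
        peak_idx = {int(t) for t in times}
        assert set(np.flatnonzero(curve.values == 1.0)) == peak_idx

    def test_overlap_takes_maximum(self):
        curve = encode_events(stream([1000.0, 1050.0]), 3000, 1000.0)
        assert curve.values.max() == 1.0
        # midpoint: max of the two Gaussians, not their sum
        expected = np.exp(-(25.0**2) / (2 * 53.3**2))
        assert curve.values[1025] == pytest.approx(expected, rel=1e-12)

    def test_event_outside_window_raises(self):
        with pytest.raises(ValueError, match="outside"):
            encode_events(stream([20000.0]), 10000, 1000.0)

    def test_off_grid_event_evaluated_exactly(self):
        curve = encode_events(stream([5004.4]), 10000, 1000.0)
        expected = np.exp(-(0.4**2) / (2 * 53.3**2))
        assert curve.values[5004] == pytest.approx(expected, rel=1e-12)


def brute_force_decode(values, rate_hz, min_height, min_interval_ms):
    """Exhaustively choose the admissible local-maxima subset maximising
    summed height (ties: prefer earlier/lexicographically smaller)."""
    n = values.size
    peaks = []
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            j = i
            while j < n - 1 and values[j + 1] == values[j]:
                j += 1
            if j < n - 1 and values[j + 1] < values[j]:
                if values[i] >= min_height:
                    peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    min_gap = min_interval_ms * rate_hz / 1000.0
    best, best_key = (), None
    for r in range(len(peaks) + 1):
        for subset in itertools.combinations(peaks, r):
            if any(b - a < min_gap for a, b in zip(subset, subset[1:])):
                continue
            key = (-sum(values[list(subset)]), subset)
            if best_key is None or key < best_key:
                best, best_key = subset, key
    return np.asarray(best, dtype=float) * (1000.0 / rate_hz)


def gaussian_bumps(n, rate_hz, centers_ms, heights, sigma_ms=53.3):
    t = np.arange(n) / rate_hz * 1000.0
    v = np.zeros(n)
    for c, h in zip(centers_ms, heights):
        v = np.maximum(v, h * np.exp(-((t - c) ** 2) / (2 * sigma_ms**2)))
    return v


class TestDecode:
    def test_single_bump_detected_at_centre(self):
        v = gaussian_bumps(10000, 1000.0, [5000.0], [1.0])
        got = decode_peaks(ConfidenceCurve(v, 1000.0, "L", "HS"))
        np.testing.assert_array_equal(got.times(), [5000.0])

    def test_below_threshold_ignored(self):
        v = gaussian_bumps(10000, 1000.0, [5000.0], [0.2])
        got = decode_peaks(ConfidenceCurve(v, 1000.0, "L", "HS"))
        assert len(got) == 0

    def test_close_peaks_keep_higher(self):
        v = gaussian_bumps(8000, 1000.0, [3000.0, 3500.0], [0.9, 0.8])
        got = decode_peaks(ConfidenceCurve(v, 1000.0, "L", "HS"))
        np.testing.assert_array_equal(got.times(), [3000.0])

    def test_empty_curve_empty_set(self):
        got = decode_peaks(ConfidenceCurve(np.zeros(100), 1000.0, "L", "HS"))
        assert len(got) == 0

    def test_plateau_reports_centre(self):
        v = np.zeros(200)
        v[80:91] = 0.5  # 11-sample plateau centred at 85
        got = decode_peaks(ConfidenceCurve(v, 1000.0, "L", "HS"),
                           min_interval_ms=10.0)
        np.testing.assert_array_equal(got.times(), [85.0])

    def test_equal_heights_keep_earlier(self):
        v = gaussian_bumps(4000, 1000.0, [1000.0, 1600.0], [0.8, 0.8])
        got = decode_peaks(ConfidenceCurve(v, 1000.0, "L", "HS"))
        np.testing.assert_array_equal(got.times(), [1000.0])

    def test_matches_scipy_on_tie_free_curves(self, rng):
        """Independent cross-check against scipy's greedy peak selection."""
        from scipy.signal import find_peaks

        for _ in range(50):
            v = rng.random(3000)
            curve = ConfidenceCurve(v, 1000.0, "L", "HS")
            got = decode_peaks(curve, min_height=0.5, min_interval_ms=100.0)
            idx, _ = find_peaks(v, height=0.5, distance=100)
            np.testing.assert_array_equal(got.times(), idx.astype(float))

    def test_matches_brute_force_oracle_on_gait_like_curves(self, rng):
        # true peaks every ~2 s at heights 0.8-1.0; artifact bumps stay
        # below every true peak and within the exclusion window of at
        # least one, so the greedy decode provably coincides with the
        # exhaustive max-summed-height subset the oracle computes
        n, rate = 1000, 100.0  # 10 s keeps exhaustive enumeration tractable
        for _ in range(200):
            t, centers, heights = 500.0, [], []
            while t < 9000.0:
                centers.append(t)
                heights.append(rng.uniform(0.8, 1.0))
                if rng.random() < 0.4:  # artifact bump after this stride
                    centers.append(t + rng.uniform(600.0, 950.0))
                    heights.append(rng.uniform(0.05, 0.7))
                t += 2000.0 + rng.normal(0.0, 50.0)
            v = gaussian_bumps(n, rate, centers, heights)
            curve = ConfidenceCurve(v, rate, "L", "HS")
            got = decode_peaks(curve).times()
            want = brute_force_decode(v, rate, 0.3, 1000.0)
            np.testing.assert_array_equal(got, want)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_spacing_respects_min_interval(self, seed):
        rng = np.random.default_rng(seed)
        v = np.clip(rng.normal(0.3, 0.3, 2000), 0, None)
        got = decode_peaks(ConfidenceCurve(v, 1000.0, "L", "HS"),
                           min_height=0.3, min_interval_ms=150.0)
        t = got.times()
        assert np.all(np.diff(t) >= 150.0)


class TestEncodeDecodeIdentity:
    def test_identity_for_well_separated_events(self):
        times = [1000.0, 3200.0, 5400.0, 7600.0]
        curve = encode_events(stream(times), 10000, 1000.0)
        got = decode_peaks(curve)
        np.testing.assert_array_equal(got.times(), times)

    @given(st.lists(st.floats(1000.0, 28000.0), min_size=1, max_size=8))
    @settings(max_examples=40, deadline=None)
    def test_identity_property(self, raw_times):
        times = sorted(round(t) for t in raw_times)
        # enforce spacing > max(min_interval, 8 sigma)
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] > 1100.0:
                kept.append(t)
        curve = encode_events(stream(kept), 30000, 1000.0)
        got = decode_peaks(curve)
        np.testing.assert_array_equal(got.times(), kept)


class TestCorrelation:
    def test_identical_curves(self):
        c = encode_events(stream([5000.0]), 10000, 1000.0)
        assert curve_correlation(c, c) == pytest.approx(1.0)

    def test_negated_curve(self):
        c = encode_events(stream([5000.0]), 10000, 1000.0)
        neg = ConfidenceCurve(-c.values, 1000.0, "L", "HS")
        assert curve_correlation(c, neg) == pytest.approx(-1.0)

    def test_offset_gaussians_match_direct_summation(self):
        a = encode_events(stream([5000.0]), 10000, 1000.0)
        b = encode_events(stream([5053.3]), 10000, 1000.0)
        x, y = a.values, b.values
        xc, yc = x - x.mean(), y - y.mean()
        expected = float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))
        assert curve_correlation(a, b) == pytest.approx(expected, rel=1e-12)

    def test_constant_curve_rejected(self):
        c = ConfidenceCurve(np.ones(100), 1000.0, "L", "HS")
        d = ConfidenceCurve(np.arange(100.0), 1000.0, "L", "HS")
        with pytest.raises(ValueError, match="constant"):
            curve_correlation(c, d)

    def test_length_mismatch_rejected(self):
        c = ConfidenceCurve(np.arange(10.0), 1000.0, "L", "HS")
        d = ConfidenceCurve(np.arange(11.0), 1000.0, "L", "HS")
        with pytest.raises(ValueError, match="length"):
            curve_correlation(c, d)
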