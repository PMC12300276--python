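"""Punch detection, best-trial selection and the end-of-punch landmark."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from emgseq import (
    MagnitudeSeries,
    PunchEvent,
    average_event_magnitude,
    detect_punches,
    end_of_punch,
    magnitude,
    select_best,
)

RATE = 142.0


def _series(mag, rate=RATE):
    mag = np.asarray(mag, dtype=float)
    return MagnitudeSeries(time=np.arange(len(mag)) / rate, mag=mag)


def _spiky(spike_times, height=25.0, total=None, rate=RATE):
    total = total or (max(spike_times) + 2.0)
    n = int(total * rate)
    mag = np.full(n, 0.5)
    for t in spike_times:
        mag[int(round(t * rate))] = height
    return _series(mag)


class TestMagnitude:
    @pytest.mark.parametrize(
        "xyz,expected",
        [((3.0, 4.0, 0.0), 5.0), ((0.0, 0.0, 0.0), 0.0),
         ((1.0, 1.0, 1.0), np.sqrt(3.0))],
    )
    def test_pointwise_norm(self, xyz, expected):
        x, y, z = (np.full(4, v) for v in xyz)
        np.testing.assert_allclose(magnitude(x, y, z).mag, expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            magnitude(np.zeros(3), np.zeros(3), np.zeros(4))

    @given(
        st.lists(
            st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
            min_size=1, max_size=20,
        ),
        st.permutations([0, 1, 2]),
        st.tuples(*[st.sampled_from([-1.0, 1.0]) for _ in range(3)]),
    )
    def test_invariant_under_axis_permutation_and_sign_flip(self, pts, perm, signs):
        arr = np.array(pts)
        base = magnitude(arr[:, 0], arr[:, 1], arr[:, 2]).mag
        flipped = arr[:, perm] * np.array(signs)
        other = magnitude(flipped[:, 0], flipped[:, 1], flipped[:, 2]).mag
        np.testing.assert_allclose(other, base, rtol=1e-12)


class TestDetectPunches:
    def test_twenty_spikes_detected(self):
        times = [2.0 + 5.0 * i for i in range(20)]
        events = detect_punches(_spiky(times), threshold=5.0, min_separation=2.0)
        assert len(events) == 20
        np.testing.assert_allclose(
            [e.peak_time for e in events], times, atol=1.5 / RATE
        )

    def test_flat_signal_yields_no_events(self):
        assert detect_punches(_series(np.full(500, 0.1)), 5.0, 2.0) == []

    def test_close_spikes_merge_keeping_larger(self):
        mag = np.full(int(5 * RATE), 0.5)
        mag[int(1.0 * RATE)] = 10.0
        mag[int(1.5 * RATE)] = 20.0
        events = detect_punches(_series(mag), 5.0, min_separation=2.0)
        assert len(events) == 1
        assert events[0].peak_mag == 20.0
        assert events[0].peak_time == pytest.approx(1.5, abs=1 / RATE)

    def test_events_returned_in_time_order(self):
        times = [1.0, 4.0, 7.0, 10.0]
        events = detect_punches(_spiky(times), 5.0, 2.0)
        assert [e.peak_time for e in events] == sorted(e.peak_time for e in events)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            detect_punches(_series(np.ones(10)), threshold=0.0)
        with pytest.raises(ValueError):
            detect_punches(_series(np.ones(10)), threshold=1.0, min_separation=0.0)


def _event(t, m):
    return PunchEvent(peak_time=t, peak_mag=m, window=(t - 0.1, t + 0.1))


class TestSelectBest:
    def test_five_largest_of_twenty(self, rng):
        best = [25.14, 25.20, 25.48, 25.52, 25.79]
        mags = best + list(rng.uniform(20.0, 25.0, 15))
        rng.shuffle(mags)
        events = [_event(2.0 + i, m) for i, m in enumerate(mags)]
        sel = select_best(events, 5)
        assert sorted(e.peak_mag for e in sel) == pytest.approx(best)

    def test_chronological_output(self, rng):
        events = [_event(float(i), m) for i, m in enumerate(rng.uniform(1, 30, 12))]
        sel = select_best(events, 4)
        assert [e.peak_time for e in sel] == sorted(e.peak_time for e in sel)

    def test_k_zero_gives_empty(self):
        assert select_best([_event(1.0, 5.0)], 0) == []

    def test_k_beyond_events_errors(self):
        with pytest.raises(ValueError, match="only 1"):
            select_best([_event(1.0, 5.0)], 2)

    def test_equal_peaks_at_cut_keep_earlier(self):
        events = [_event(1.0, 10.0), _event(2.0, 10.0), _event(3.0, 20.0)]
        sel = select_best(events, 2)
        assert [e.peak_time for e in sel] == [1.0, 3.0]

    @given(st.lists(st.floats(0.1, 100.0), min_size=0, max_size=50,
                    unique=True),
           st.integers(0, 50))
    def test_matches_brute_force_sort_oracle(self, mags, k):
        events = [_event(float(i), m) for i, m in enumerate(mags)]
        if k > len(events):
            with pytest.raises(ValueError):
                select_best(events, k)
            return
        oracle = sorted(sorted(events, key=lambda e: -e.peak_mag)[:k],
                        key=lambda e: e.peak_time)
        assert select_best(events, k) == oracle


def _pulse(center_idx, height, n, rate=RATE):
    mag = np.full(n, 1.0)
    mag[center_idx] = height
    return mag


class TestAverageEventMagnitude:
    def test_identical_pulses_average_to_one_pulse(self):
        n = int(20 * RATE)
        mag = np.full(n, 1.0)
        centers = [int((2 + 4 * i) * RATE) for i in range(5)]
        for c in centers:
            mag[c] = 10.0
        series = _series(mag)
        events = [_event(series.time[c], 10.0) for c in centers]
        avg = average_event_magnitude(series, events, span=(0.5, 0.5))
        assert avg.mag.max() == pytest.approx(10.0)
        assert avg.time[np.argmax(avg.mag)] == pytest.approx(0.0)

    def test_linearity_of_pulse_heights(self):
        n = int(10 * RATE)
        mag = np.full(n, 0.0)
        c1, c2 = int(2 * RATE), int(6 * RATE)
        mag[c1], mag[c2] = 1.0, 3.0
        series = _series(mag)
        events = [_event(series.time[c1], 1.0), _event(series.time[c2], 3.0)]
        avg = average_event_magnitude(series, events, span=(0.5, 0.5))
        assert avg.mag[np.argmin(np.abs(avg.time))] == pytest.approx(2.0)

    def test_span_exceeding_bounds_errors(self):
        series = _series(np.full(100, 1.0))
        with pytest.raises(ValueError, match="bounds"):
            average_event_magnitude(series, [_event(0.05, 1.0)], span=(0.5, 0.5))


class TestEndOfPunch:
    def _biphasic(self, min_offset=0.08):
        t = np.arange(-71, 72) / RATE
        mag = np.full_like(t, 1.0)
        mag[np.argmin(np.abs(t))] = 25.0
        k = int(np.argmin(np.abs(t - min_offset)))
        mag[k] = 0.1
        return MagnitudeSeries(time=t, mag=mag), t[k]

    def test_minimum_at_constructed_offset(self):
        avg, true_t = self._biphasic(0.08)
        eop = end_of_punch(avg, search_window=0.3)
        assert eop.time == pytest.approx(true_t)
        assert eop.offset_from_peak == pytest.approx(true_t)

    def test_monotone_decreasing_tail_hits_window_end(self):
        t = np.arange(-14, 57) / RATE
        mag = np.maximum(2.0 - 2.0 * t, 0.0) + 0.5
        avg = MagnitudeSeries(time=t, mag=mag)
        eop = end_of_punch(avg, search_window=0.3)
        in_window = t[(t > 0) & (t <= 0.3)]
        assert eop.time == pytest.approx(in_window[-1])

    def test_equal_minima_take_earlier(self):
        t = np.arange(-14, 43) / RATE
        mag = np.full_like(t, 1.0)
        i1 = int(np.argmin(np.abs(t - 0.08)))
        i2 = int(np.argmin(np.abs(t - 0.15)))
        mag[i1] = mag[i2] = 0.2
        eop = end_of_punch(MagnitudeSeries(time=t, mag=mag), 0.3)
        assert eop.time == pytest.approx(t[i1])

    def test_empty_window_errors(self):
        t = np.arange(-14, 1) / RATE  # nothing after the peak
        with pytest.raises(ValueError, match="window"):
            end_of_punch(MagnitudeSeries(time=t, mag=np.ones_like(t)), 0.3)
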