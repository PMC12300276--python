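"""Punch-event detection on the forearm accelerometer.

A punch shows up on the forearm sensor as a large positive excursion of the
acceleration magnitude (tens of g) followed, at impact, by a sharp dip where
the forearm decelerates against the target.  The trial-averaged magnitude
around the peak locates that dip — the *end of punch* — which defines time
zero for all EMG activation times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MagnitudeSeries",
    "PunchEvent",
    "EndOfPunch",
    "magnitude",
    "detect_punches",
    "select_best",
    "average_event_magnitude",
    "end_of_punch",
]


@dataclass
class MagnitudeSeries:
    """Acceleration magnitude (multiples of g) on a time axis in seconds."""

    time: np.ndarray
    mag: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        if self.time.shape != self.mag.shape:
            raise ValueError("time and mag must have equal length")
        if np.any(self.mag < 0):
            raise ValueError("magnitude must be non-negative")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass(frozen=True)
class PunchEvent:
    """One detected punch: supra-threshold excursion of the magnitude."""

    peak_time: float
    peak_mag: float
    window: tuple[float, float]


@dataclass(frozen=True)
class EndOfPunch:
    """Impact landmark: the magnitude minimum after the punch's peak."""

    time: float
    offset_from_peak: float


def magnitude(ax: np.ndarray, ay: np.ndarray, az: np.ndarray,
              time: np.ndarray | None = None) -> MagnitudeSeries:
    """Pointwise Euclidean norm of the three acceleration axes.

    ``accMag = sqrt(acc_x^2 + acc_y^2 + acc_z^2)``, in multiples of g.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError("the three axis series must have equal length")
    mag = np.sqrt(ax**2 + ay**2 + az**2)
    if time is None:
        time = np.arange(len(mag), dtype=float)
    return MagnitudeSeries(time=np.asarray(time, dtype=float), mag=mag)


def detect_punches(
    mag: MagnitudeSeries,
    threshold: float = 5.0,
    min_separation: float = 2.0,
) -> list[PunchEvent]:
    """Detect punches as supra-threshold excursions of the magnitude.

    One event per contiguous region with ``mag > threshold``; events whose
    peaks lie closer than ``min_separation`` seconds are merged keeping the
    larger peak (ties: the earlier).  Defaults (5 g, 2 s) sit far below the
    ~25 g peaks and far inside the ~5 s inter-punch spacing of a typical
    session.  A flat signal yields an empty list.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    above = mag.mag > threshold
    if not above.any():
        return []
    # contiguous supra-threshold runs
    idx = np.flatnonzero(above)
    run_starts = [idx[0]]
    run_ends = []
    for a, b in zip(idx[:-1], idx[1:]):
        if b != a + 1:
            run_ends.append(a)
            run_starts.append(b)
    run_ends.append(idx[-1])

    events: list[PunchEvent] = []
    for s, e in zip(run_starts, run_ends):
        seg = mag.mag[s : e + 1]
        k = int(np.argmax(seg))
        events.append(
            PunchEvent(
                peak_time=float(mag.time[s + k]),
                peak_mag=float(seg[k]),
                window=(float(mag.time[s]), float(mag.time[e])),
            )
        )
    # merge peaks closer than min_separation, keeping the larger
    merged: list[PunchEvent] = []
    for ev in events:
        if merged and ev.peak_time - merged[-1].peak_time < min_separation:
            prev = merged[-1]
            keep = prev if prev.peak_mag >= ev.peak_mag else ev
            merged[-1] = PunchEvent(
                peak_time=keep.peak_time,
                peak_mag=keep.peak_mag,
                window=(prev.window[0], ev.window[1]),
            )
        else:
            merged.append(ev)
    return merged


def select_best(events: list[PunchEvent], k: int) -> list[PunchEvent]:
    """The ``k`` events with the largest peak magnitude, in time order.

    Equal peaks at the cut keep the earlier event.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(events):
        raise ValueError(f"asked for {k} events but only {len(events)} detected")
    # stable sort descending by magnitude: earlier event wins ties
    order = sorted(range(len(events)), key=lambda i: -events[i].peak_mag)
    chosen = sorted(order[:k])
    return [events[i] for i in chosen]


def average_event_magnitude(
    mag: MagnitudeSeries,
    events: list[PunchEvent],
    span: tuple[float, float] = (0.5, 0.5),
) -> MagnitudeSeries:
    """Average the magnitude across events, aligned at each event's peak.

    ``span = (before, after)`` in seconds around the peak.  The returned
    series lives on a relative time axis with the common peak at 0.
    """
    if not events:
        raise ValueError("no events to average")
    before, after = span
    dt = 1.0 / mag.rate
    n_before = int(round(before / dt))
    n_after = int(round(after / dt))
    rows = []
    for ev in events:
        c = int(np.argmin(np.abs(mag.time - ev.peak_time)))
        lo, hi = c - n_before, c + n_after
        if lo < 0 or hi >= len(mag.mag):
            raise ValueError(
                f"span {span} around the event at {ev.peak_time:.3f} s "
                "exceeds the recording bounds"
            )
        rows.append(mag.mag[lo : hi + 1])
    avg = np.mean(rows, axis=0)
    rel = (np.arange(-n_before, n_after + 1)) * dt
    return MagnitudeSeries(time=rel, mag=avg)


def end_of_punch(avg: MagnitudeSeries, search_window: float = 0.3) -> EndOfPunch:
    """Locate the impact minimum of the peak-aligned averaged magnitude.

    Returns the time of the global minimum within ``(peak, peak +
    search_window]``, where the peak is at relative time 0.  Ties keep the
    earlier minimum.  The offset from the peak is recorded so that each
    trial's end-of-punch is ``trial peak_time + offset``.
    """
    if search_window <= 0:
        raise ValueError("search_window must be positive")
    mask = (avg.time > 0) & (avg.time <= search_window)
    if not mask.any():
        raise ValueError("empty post-peak search window")
    idx = np.flatnonzero(mask)
    k = idx[int(np.argmin(avg.mag[idx]))]  # argmin returns first on ties
    return EndOfPunch(time=float(avg.time[k]), offset_from_peak=float(avg.time[k]))
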