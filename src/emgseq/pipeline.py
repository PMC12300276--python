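"""Per-muscle EMG processing: median segment, TKEO envelope, activation levels.

For each muscle the representative signal is the pointwise median of the
0.5 s segments ending at the end-of-punch of the best trials.  The median
is band-passed (30-300 Hz, order-6 Butterworth, zero-phase), transformed
with the Teager-Kaiser energy operator

    Psi(x_n) = x_n^2 - x_{n+1} * x_{n-1},

low-passed (7 Hz, order-4, zero-phase) into a smooth envelope, min-max
normalized to [0, 1], and discretized into four activation levels at
0.25 / 0.5 / 0.75.  Onset is the first instant the normalized envelope
reaches 0.25 (the level-0 to level-1 transition).

All filtering is zero-phase (forward-backward) so that envelope timing is
not biased by filter group delay; segments are reflection-padded before
filtering to suppress edge transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "Segment",
    "EnvelopeSeries",
    "ActivationLevelSeries",
    "extract_segment",
    "median_segments",
    "bandpass",
    "tkeo",
    "smooth",
    "normalize01",
    "discretize",
    "onset_time",
    "max_activation_time",
    "process_segment",
    "SEGMENT_DURATION_S",
    "ONSET_THRESHOLD",
]

#: default analysis-window length before the end of punch
SEGMENT_DURATION_S = 0.5
#: normalized-amplitude threshold defining activation onset (level 1 entry)
ONSET_THRESHOLD = 0.25

#: treat an envelope with a smaller min-max range than this as silent
_SILENT_RANGE = 1e-12


@dataclass
class Segment:
    """A fixed-length EMG window ending at the end-of-punch (time 0)."""

    muscle: tuple[str, str]  # (side, abbreviation)
    time_rel: np.ndarray  # seconds in [-duration, 0]
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.time_rel = np.asarray(self.time_rel, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.time_rel.shape != self.samples.shape:
            raise ValueError("time_rel and samples must have equal length")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_rel)))


@dataclass
class EnvelopeSeries:
    """One muscle's processed segment at every pipeline stage."""

    muscle: tuple[str, str]
    time_rel: np.ndarray
    filtered: np.ndarray
    tkeo: np.ndarray
    smooth: np.ndarray
    normalized: np.ndarray
    silent: bool = False


@dataclass
class ActivationLevelSeries:
    """Quartile-discretized activation levels (0-3) over the segment."""

    muscle: tuple[str, str]
    time_rel: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        bad = set(np.unique(self.levels)) - {0, 1, 2, 3}
        if bad:
            raise ValueError(f"levels outside 0-3: {sorted(bad)}")


def extract_segment(
    emg: np.ndarray,
    time: np.ndarray,
    end_time: float,
    duration: float = SEGMENT_DURATION_S,
    muscle: tuple[str, str] = ("", ""),
) -> Segment:
    """Cut the window of ``duration`` seconds ending at ``end_time``.

    The last sample is the one at (or nearest before) ``end_time``; the
    relative time axis ends at exactly 0.  Raises if the recording holds
    insufficient pre-history.
    """
    time = np.asarray(time, dtype=float)
    emg = np.asarray(emg, dtype=float)
    rate = 1.0 / float(np.median(np.diff(time)))
    n = int(round(duration * rate))
    i_end = int(np.searchsorted(time, end_time + 1e-12, side="right") - 1)
    if i_end < 0:
        raise ValueError(f"end_time {end_time:.3f} s precedes the recording")
    i_start = i_end - n + 1
    if i_start < 0:
        raise ValueError(
            f"segment of {duration} s ending at {end_time:.3f} s reaches "
            "before the start of the recording"
        )
    time_rel = (np.arange(n) - (n - 1)) / rate
    return Segment(muscle=muscle, time_rel=time_rel, samples=emg[i_start : i_end + 1])


def median_segments(segments: list[Segment]) -> Segment:
    """Pointwise median across same-muscle, same-length segments.

    The median is robust to a single outlier trial, which is why it is
    preferred over the mean for the representative signal.
    """
    if not segments:
        raise ValueError("no segments")
    n = len(segments[0].samples)
    muscle = segments[0].muscle
    for s in segments[1:]:
        if len(s.samples) != n:
            raise ValueError("segments differ in length")
        if s.muscle != muscle:
            raise ValueError(f"mixed muscles: {muscle} vs {s.muscle}")
    stacked = np.vstack([s.samples for s in segments])
    return Segment(
        muscle=muscle,
        time_rel=segments[0].time_rel.copy(),
        samples=np.median(stacked, axis=0),
    )


def _zero_phase(sos: np.ndarray, x: np.ndarray, rate: float, pad_s: float = 0.3) -> np.ndarray:
    """Forward-backward filtering with explicit reflection padding."""
    pad = min(int(round(pad_s * rate)), len(x) - 1)
    if pad > 0:
        xp = np.pad(x, pad, mode="reflect")
    else:
        xp = x
    y = signal.sosfiltfilt(sos, xp, padlen=0)
    return y[pad : len(y) - pad] if pad > 0 else y


def bandpass(
    x: np.ndarray,
    rate: float,
    low: float = 30.0,
    high: float = 300.0,
    order: int = 6,
    pad_s: float = 0.3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 30-300 Hz, order 6).

    ``order`` is the overall filter order; a band-pass of order 6 uses 3
    second-order sections per direction.  Zero-phase application doubles
    the effective attenuation.
    """
    if not 0 < low < high < rate / 2:
        raise ValueError(
            f"invalid band edges ({low}, {high}) Hz at rate {rate} Hz"
        )
    if order % 2:
        raise ValueError("band-pass order must be even")
    sos = signal.butter(order // 2, [low, high], btype="bandpass", fs=rate, output="sos")
    return _zero_phase(sos, np.asarray(x, dtype=float), rate, pad_s)


def tkeo(x: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy operator, ``Psi(x_n) = x_n^2 - x_{n+1} x_{n-1}``.

    For a sinusoid ``A sin(w n)`` the output is the constant ``A^2 sin^2 w``,
    so bursts stand out by both amplitude and frequency.  The operator is
    undefined at the first and last sample; those copy their nearest
    interior value so the length is preserved without fabricating energy.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("TKEO needs at least 3 samples")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[2:] * x[:-2]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def smooth(
    x: np.ndarray,
    rate: float,
    cutoff: float = 7.0,
    order: int = 4,
    pad_s: float = 0.3,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (default 7 Hz, order 4) envelope."""
    if not 0 < cutoff < rate / 2:
        raise ValueError(f"invalid cutoff {cutoff} Hz at rate {rate} Hz")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=rate, output="sos")
    return _zero_phase(sos, np.asarray(x, dtype=float), rate, pad_s)


def normalize01(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min-max scale to [0, 1]; a (near-)constant input is flagged silent.

    Returns ``(normalized, silent)``.  Silent channels map to all zeros;
    ranges below 1e-12 count as constant to avoid dividing by rounding
    noise.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty series")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < _SILENT_RANGE:
        return np.zeros_like(x), True
    return (x - lo) / (hi - lo), False


def discretize(normalized: np.ndarray) -> np.ndarray:
    """Map normalized amplitude to activation levels 0-3.

    0 below 0.25, 1 on [0.25, 0.5), 2 on [0.5, 0.75), 3 at and above 0.75.
    """
    x = np.asarray(normalized, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("normalized values must lie in [0, 1]")
    return np.digitize(x, [0.25, 0.5, 0.75], right=False).astype(np.int8)


def onset_time(
    normalized: np.ndarray,
    time_rel: np.ndarray,
    threshold: float = ONSET_THRESHOLD,
    silent: bool = False,
) -> float | None:
    """Time the normalized envelope first reaches ``threshold`` (>= 0.25).

    Coincides exactly with the level-0 to level-1 transition of the
    discretized series.  Silent channels have no onset (``None``).
    """
    if silent:
        return None
    hits = np.flatnonzero(np.asarray(normalized) >= threshold)
    if len(hits) == 0:
        return None
    return float(np.asarray(time_rel)[hits[0]])


def max_activation_time(normalized: np.ndarray, time_rel: np.ndarray) -> float:
    """Time of the global maximum; the earliest index wins ties."""
    x = np.asarray(normalized)
    if len(x) == 0:
        raise ValueError("empty series")
    return float(np.asarray(time_rel)[int(np.argmax(x))])


def process_segment(
    segment: Segment,
    band: tuple[float, float] = (30.0, 300.0),
    band_order: int = 6,
    smooth_cutoff: float = 7.0,
    smooth_order: int = 4,
    pad_s: float = 0.3,
) -> tuple[EnvelopeSeries, ActivationLevelSeries]:
    """Run one median segment through the full envelope pipeline."""
    rate = segment.sampling_rate
    filt = bandpass(segment.samples, rate, *band, order=band_order, pad_s=pad_s)
    psi = tkeo(filt)
    sm = smooth(psi, rate, cutoff=smooth_cutoff, order=smooth_order, pad_s=pad_s)
    norm, silent = normalize01(sm)
    env = EnvelopeSeries(
        muscle=segment.muscle,
        time_rel=segment.time_rel.copy(),
        filtered=filt,
        tkeo=psi,
        smooth=sm,
        normalized=norm,
        silent=silent,
    )
    levels = ActivationLevelSeries(
        muscle=segment.muscle,
        time_rel=segment.time_rel.copy(),
        levels=discretize(norm),
    )
    return env, levels
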