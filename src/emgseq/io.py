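"""Reading and writing signal tables and the channel-map configuration.

Wireless sEMG/accelerometer systems export delimited-text tables: one EMG
table (16 channels, 2000 Hz) and one tri-axial accelerometer table per
sensor (142 Hz), each with a leading time (or sample-index) column.  Export
dialects vary by vendor and locale, so the reader auto-detects the
delimiter and tolerates decimal commas.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SignalBundle",
    "ChannelMapEntry",
    "ChannelMap",
    "read_signal_table",
    "write_signal_table",
    "load_channel_map",
    "default_channel_map",
    "EMG_RATE_HZ",
    "ACCEL_RATE_HZ",
]

#: Native sampling rates of the acquisition system.
EMG_RATE_HZ = 2000.0
ACCEL_RATE_HZ = 142.0

Role = Literal["emg", "accel"]


@dataclass
class SignalBundle:
    """A time-indexed multichannel recording.

    Parameters
    ----------
    role
        ``"emg"`` (voltages, arbitrary mV-scale units) or ``"accel"``
        (per-axis acceleration in multiples of g; channels come in
        (x, y, z) triplets per sensor).
    sampling_rate
        Samples per second.
    time
        Strictly increasing time axis in seconds, one entry per sample.
    samples
        2-D array, shape ``(n_samples, n_channels)``.
    labels
        One label per channel, same order as the columns of ``samples``.
    """

    role: Role
    sampling_rate: float
    time: np.ndarray
    samples: np.ndarray
    labels: list[str]

    #: relative tolerance on sample-spacing jitter
    rate_tolerance: float = 0.01

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != self.time.shape[0]:
            raise ValueError(
                f"samples ({self.samples.shape[0]} rows) do not match the "
                f"time axis ({self.time.shape[0]} entries)"
            )
        if len(self.labels) != self.samples.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.samples.shape[1]} channels"
            )
        if self.role not in ("emg", "accel"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.role == "accel" and self.samples.shape[1] % 3 != 0:
            raise ValueError(
                "accelerometer bundles carry (x, y, z) triplets per sensor; "
                f"got {self.samples.shape[1]} channels"
            )
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            nominal = 1.0 / self.sampling_rate
            if np.max(np.abs(dt - nominal)) > self.rate_tolerance * nominal:
                measured = 1.0 / np.median(dt)
                raise ValueError(
                    f"time axis spacing implies {measured:.4g} Hz but the "
                    f"bundle declares {self.sampling_rate:.4g} Hz"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if len(self.time) else 0.0

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None
        return self.samples[:, idx]

    def sensor_triplet(self, sensor: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return the (x, y, z) axes of one accelerometer sensor (0-based)."""
        if self.role != "accel":
            raise ValueError("sensor_triplet is only defined for accel bundles")
        n_sensors = self.n_channels // 3
        if not 0 <= sensor < n_sensors:
            raise IndexError(f"sensor {sensor} out of range (have {n_sensors})")
        cols = self.samples[:, 3 * sensor : 3 * sensor + 3]
        return cols[:, 0], cols[:, 1], cols[:, 2]


_SIDES = {"left": "Left", "right": "Right", "l": "Left", "r": "Right"}


@dataclass(frozen=True)
class ChannelMapEntry:
    channel_id: int
    side: str  # "Left" | "Right"
    muscle: str  # abbreviation, e.g. "MG"
    function: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.side, self.muscle)


@dataclass
class ChannelMap:
    """Assignment of EMG channels to (side, muscle) pairs."""

    entries: list[ChannelMapEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.channel_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate channel_id(s): {dup}")
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (side, muscle) assignment")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_channel(self, channel_id: int) -> ChannelMapEntry:
        for e in self.entries:
            if e.channel_id == channel_id:
                return e
        raise KeyError(f"channel {channel_id} not in map")

    def order_of(self, side: str, muscle: str) -> int:
        """Position of a (side, muscle) pair in map order (tie-break key)."""
        for i, e in enumerate(self.entries):
            if e.key == (side, muscle):
                return i
        raise KeyError(f"({side}, {muscle}) not in map")

    @property
    def muscles(self) -> list[tuple[str, str]]:
        return [e.key for e in self.entries]


# Sensor-unit layout used throughout: 16 electrodes, 8 muscles on each side,
# odd channels on the right, the paired even channel on the left.
_DEFAULT_LAYOUT: list[tuple[str, str]] = [
    ("MG", "Ankle plantar flexion"),
    ("RF", "Knee extension"),
    ("EO", "Trunk rotation"),
    ("PM", "Arm adduction"),
    ("AD", "Shoulder anteflexion"),
    ("BB", "Elbow stabilization"),
    ("LT", "Elbow extension/stabilization"),
    ("ECR", "Wrist stabilization"),
]

MUSCLE_NAMES = {
    "MG": "Gastrocnemius, medial head",
    "RF": "Rectus femoris",
    "EO": "Abdominal External Oblique",
    "PM": "Major Pectoral",
    "AD": "Deltoid, anterior head",
    "BB": "Biceps Brachii",
    "LT": "Triceps Brachii, lateral head",
    "ECR": "Extensor Carpi Radialis",
}


def default_channel_map() -> ChannelMap:
    """The built-in 16-electrode map (8 muscles x 2 sides)."""
    entries = []
    cid = 1
    for muscle, function in _DEFAULT_LAYOUT:
        for side in ("Right", "Left"):
            entries.append(ChannelMapEntry(cid, side, muscle, function))
            cid += 1
    return ChannelMap(entries)


def load_channel_map(path: str | Path | None = None) -> ChannelMap:
    """Load a channel map from YAML or JSON; ``None`` returns the default.

    The file holds a list of entries, each with ``channel`` (int), ``side``
    (left/right, any case), ``muscle`` (abbreviation) and optionally
    ``function``.
    """
    if path is None:
        return default_channel_map()
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if isinstance(raw, dict) and "channels" in raw:
        raw = raw["channels"]
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: expected a non-empty list of channel entries")
    entries = []
    for item in raw:
        side_token = str(item["side"]).strip().lower()
        if side_token not in _SIDES:
            raise ValueError(f"{path}: unknown side token {item['side']!r}")
        entries.append(
            ChannelMapEntry(
                channel_id=int(item["channel"]),
                side=_SIDES[side_token],
                muscle=str(item["muscle"]).strip(),
                function=str(item.get("function", "")),
            )
        )
    return ChannelMap(entries)


def _sniff_delimiter(header: str) -> str:
    # Prefer tab, then semicolon, then comma: a semicolon-delimited European
    # export may also contain decimal commas, so comma is checked last.
    for cand in ("\t", ";", ","):
        if cand in header:
            return cand
    return r"\s+"


def _looks_like_sample_index(col: np.ndarray) -> bool:
    if len(col) < 2:
        return False
    d = np.diff(col)
    return bool(np.allclose(d, 1.0) and np.allclose(col, np.round(col)))


def read_signal_table(
    path: str | Path,
    role: Role,
    expected_rate: float,
    rate_tolerance: float = 0.01,
) -> SignalBundle:
    """Read a delimited-text signal table into a :class:`SignalBundle`.

    The first column is the time axis in seconds, or a 0/1-based sample
    index, in which case time is synthesized as ``index / expected_rate``.
    Tab-, semicolon- and comma-delimited files with one header row are
    accepted; decimal commas are converted.

    Raises
    ------
    ValueError
        On an empty file, ragged rows, non-numeric cells, or a measured
        sampling rate deviating from ``expected_rate`` beyond
        ``rate_tolerance`` (relative).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"{path}: no data rows")
    sep = _sniff_delimiter(lines[0])
    df = pd.read_csv(_stdio.StringIO(text), sep=sep, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one channel")
    # decimal-comma exports parse as strings: convert
    for col in df.columns:
        if df[col].dtype == object:
            converted = pd.to_numeric(
                df[col].astype(str).str.replace(",", ".", regex=False),
                errors="coerce",
            )
            df[col] = converted
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows or non-numeric cells")

    first = df.iloc[:, 0].to_numpy(dtype=float)
    if _looks_like_sample_index(first):
        first = first - first[0]
        time = first / expected_rate
    else:
        time = first
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: time column is not strictly increasing")
        measured = 1.0 / float(np.median(dt))
        if abs(measured - expected_rate) > rate_tolerance * expected_rate:
            raise ValueError(
                f"{path}: measured sampling rate {measured:.4g} Hz deviates "
                f"from expected {expected_rate:.4g} Hz"
            )
    samples = df.iloc[:, 1:].to_numpy(dtype=float)
    labels = [str(c) for c in df.columns[1:]]
    return SignalBundle(
        role=role,
        sampling_rate=expected_rate,
        time=time,
        samples=samples,
        labels=labels,
        rate_tolerance=max(rate_tolerance, 0.01),
    )


def write_signal_table(bundle: SignalBundle, path: str | Path) -> None:
    """Write a bundle as TSV with a one-line header (re-readable)."""
    path = Path(path)
    df = pd.DataFrame(bundle.samples, columns=bundle.labels)
    df.insert(0, "time_s", bundle.time)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def channel_map_to_json(cmap: ChannelMap) -> str:
    return json.dumps(
        [
            {
                "channel": e.channel_id,
                "side": e.side,
                "muscle": e.muscle,
                "function": e.function,
            }
            for e in cmap.entries
        ],
        indent=2,
    )
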