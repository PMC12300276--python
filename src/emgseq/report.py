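"""Activation-sequence table, session summary and the activation map.

The ordered table ranks muscles by activation onset (most negative = first
to fire, time 0 = end of punch).  The activation map draws one row per
muscle over the final half second, in four tones (darker = higher level),
with a marker at each muscle's maximal activation.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass
from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
from matplotlib.colors import BoundaryNorm, ListedColormap

from .events import PunchEvent
from .io import ChannelMap
from .pipeline import ActivationLevelSeries

__all__ = [
    "ActivationRecord",
    "SessionSummary",
    "MuscleTiming",
    "build_sequence_table",
    "summarize_peaks",
    "render_activation_map",
    "sequence_table_tsv",
]


@dataclass(frozen=True)
class ActivationRecord:
    """One row of the activation-sequence table."""

    sequence: int  # rank, 1 = first muscle to activate
    side: str
    muscle: str
    onset: float  # s, <= 0 (before end of punch)
    max_time: float  # s, time of maximal activation

    def __post_init__(self) -> None:
        if self.onset > self.max_time + 1e-12:
            raise ValueError(
                f"onset {self.onset} after maximal activation {self.max_time}"
            )


@dataclass(frozen=True)
class MuscleTiming:
    """Per-muscle timing input to the sequence table; onset None = silent."""

    side: str
    muscle: str
    onset: float | None
    max_time: float | None


@dataclass
class SessionSummary:
    """Peak magnitudes of the selected punches and their statistics."""

    selected_peaks: list[float]
    mean_peak: float
    sd_peak: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_peaks_g": [round(p, 2) for p in sorted(self.selected_peaks)],
                "mean_peak_g": round(self.mean_peak, 2),
                "sd_peak_g": round(self.sd_peak, 2),
            },
            indent=2,
        )


def build_sequence_table(
    timings: list[MuscleTiming],
    channel_map: ChannelMap,
) -> tuple[list[ActivationRecord], list[MuscleTiming]]:
    """Rank muscles by onset; silent muscles are listed apart, unranked.

    Ties in onset are broken by channel-map order (stable).  Returns
    ``(records, silent)``.
    """
    active = [t for t in timings if t.onset is not None]
    silent = [t for t in timings if t.onset is None]
    if not active:
        raise ValueError("all onsets missing: nothing to rank")
    key = lambda t: (t.onset, channel_map.order_of(t.side, t.muscle))
    ordered = sorted(active, key=key)
    records = [
        ActivationRecord(
            sequence=i + 1,
            side=t.side,
            muscle=t.muscle,
            onset=round(t.onset, 3),
            max_time=round(t.max_time, 3) if t.max_time is not None else t.onset,
        )
        for i, t in enumerate(ordered)
    ]
    return records, silent


def summarize_peaks(selected: list[PunchEvent] | list[float]) -> SessionSummary:
    """Mean and sample standard deviation (n-1) of the selected peaks."""
    if not selected:
        raise ValueError("no selected punches")
    peaks = [
        ev.peak_mag if isinstance(ev, PunchEvent) else float(ev) for ev in selected
    ]
    mean = statistics.fmean(peaks)
    sd = statistics.stdev(peaks) if len(peaks) > 1 else 0.0
    return SessionSummary(selected_peaks=peaks, mean_peak=mean, sd_peak=sd)


def sequence_table_tsv(records: list[ActivationRecord]) -> str:
    lines = ["sequence\tside\tmuscle\tonset_s\tmax_s"]
    for r in records:
        lines.append(f"{r.sequence}\t{r.side}\t{r.muscle}\t{r.onset:.3f}\t{r.max_time:.3f}")
    return "\n".join(lines) + "\n"


#: four tones of one hue, lightest = level 0 (inactive)
DEFAULT_PALETTE = ["#f4e8d8", "#d9a877", "#b06a2c", "#6b3a0e"]


def render_activation_map(
    levels: list[ActivationLevelSeries],
    path: str | Path,
    max_times: dict[tuple[str, str], float] | None = None,
    palette: list[str] = DEFAULT_PALETTE,
    title: str | None = None,
) -> Path:
    """Render the activation map (one row per muscle) to PNG or SVG.

    All series must share the time axis.  Rows appear top-to-bottom in the
    order given; a vertical white line marks each muscle's maximal
    activation when ``max_times`` is provided.  SVG output is byte-stable
    for identical inputs.
    """
    if not levels:
        raise ValueError("no level series")
    t = levels[0].time_rel
    for s in levels[1:]:
        if len(s.time_rel) != len(t) or not np.allclose(s.time_rel, t):
            raise ValueError("level series do not share a time axis")
    grid = np.vstack([s.levels for s in levels])
    n_muscles = grid.shape[0]

    cmap = ListedColormap(palette)
    norm = BoundaryNorm([-0.5, 0.5, 1.5, 2.5, 3.5], cmap.N)
    fig, ax = plt.subplots(figsize=(8, 0.4 * n_muscles + 1.2))
    extent = (float(t[0]), float(t[-1]), n_muscles - 0.5, -0.5)
    im = ax.imshow(grid, aspect="auto", cmap=cmap, norm=norm,
                   interpolation="nearest", extent=extent)
    if max_times:
        for row, s in enumerate(levels):
            mt = max_times.get(s.muscle)
            if mt is not None:
                ax.plot([mt, mt], [row - 0.5, row + 0.5], color="white", lw=1.5)
    ax.set_yticks(range(n_muscles))
    ax.set_yticklabels([f"{side} {muscle}" for side, muscle in (s.muscle for s in levels)],
                       fontsize=8)
    ax.set_xlabel("time relative to end of punch (s)")
    if title:
        ax.set_title(title)
    cbar = fig.colorbar(im, ax=ax, ticks=[0, 1, 2, 3], pad=0.01)
    cbar.set_label("activation level")
    fig.tight_layout()

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with plt.rc_context({"svg.hashsalt": "emgseq"}):
        fig.savefig(path, dpi=150, metadata={"Date": None} if path.suffix == ".svg" else None)
    plt.close(fig)
    return path
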