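"""End-to-end session analysis: from raw bundles to the sequence table.

Pipeline: forearm acceleration magnitude -> punch detection -> best-k
selection -> peak-aligned trial averaging -> end-of-punch (impact minimum)
-> per-muscle median EMG segments -> TKEO envelope -> activation levels,
onsets and the ordered sequence table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .events import (
    EndOfPunch,
    MagnitudeSeries,
    PunchEvent,
    average_event_magnitude,
    detect_punches,
    end_of_punch,
    magnitude,
    select_best,
)
from .io import ChannelMap, SignalBundle, default_channel_map
from .pipeline import (
    ActivationLevelSeries,
    EnvelopeSeries,
    SEGMENT_DURATION_S,
    extract_segment,
    max_activation_time,
    median_segments,
    onset_time,
    process_segment,
)
from .report import (
    ActivationRecord,
    MuscleTiming,
    SessionSummary,
    build_sequence_table,
    render_activation_map,
    sequence_table_tsv,
    summarize_peaks,
)

__all__ = ["AnalysisOptions", "SessionResult", "analyze_session"]


@dataclass
class AnalysisOptions:
    """Tunable parameters of the full pipeline (defaults as published use)."""

    k_best: int = 5
    detect_threshold_g: float = 5.0
    min_separation_s: float = 2.0
    avg_span_s: tuple[float, float] = (0.5, 0.5)
    eop_search_window_s: float = 0.3
    segment_duration_s: float = SEGMENT_DURATION_S
    band_hz: tuple[float, float] = (30.0, 300.0)
    band_order: int = 6
    smooth_cutoff_hz: float = 7.0
    smooth_order: int = 4
    onset_threshold: float = 0.25
    forearm_sensor: int = 0  # triplet index in the accel bundle


@dataclass
class SessionResult:
    """Everything the analysis produces for one session."""

    events: list[PunchEvent]
    selected: list[PunchEvent]
    eop: EndOfPunch
    end_times: list[float]  # per-selected-trial end-of-punch (s)
    avg_magnitude: MagnitudeSeries
    envelopes: dict[tuple[str, str], EnvelopeSeries]
    levels: dict[tuple[str, str], ActivationLevelSeries]
    records: list[ActivationRecord]
    silent: list[MuscleTiming]
    summary: SessionSummary

    @property
    def onsets(self) -> dict[tuple[str, str], float]:
        return {(r.side, r.muscle): r.onset for r in self.records}

    @property
    def sequence(self) -> list[tuple[str, str]]:
        """Muscles in activation order (first to fire first)."""
        return [(r.side, r.muscle) for r in self.records]

    def events_json(self) -> str:
        return json.dumps(
            {
                "n_events": len(self.events),
                "peak_times_s": [round(e.peak_time, 4) for e in self.events],
                "peak_mags_g": [round(e.peak_mag, 3) for e in self.events],
                "selected_peak_times_s": [round(e.peak_time, 4) for e in self.selected],
                "selected_peak_mags_g": [round(e.peak_mag, 3) for e in self.selected],
                "end_of_punch_offset_s": round(self.eop.offset_from_peak, 4),
            },
            indent=2,
        )


def _emg_channel_for(emg: SignalBundle, entry_channel_id: int, position: int) -> np.ndarray:
    """Pick the EMG column for a channel-map entry.

    Columns labelled ``ch<N>...`` are matched by channel id; otherwise the
    map's entry order indexes the columns positionally.
    """
    for i, lab in enumerate(emg.labels):
        if lab.startswith(f"ch{entry_channel_id}_") or lab == f"ch{entry_channel_id}":
            return emg.samples[:, i]
    return emg.samples[:, position]


def analyze_session(
    emg: SignalBundle,
    accel: SignalBundle,
    channel_map: ChannelMap | None = None,
    options: AnalysisOptions | None = None,
) -> SessionResult:
    """Run the complete activation-sequencing analysis on one session."""
    opts = options or AnalysisOptions()
    cmap = channel_map or default_channel_map()

    ax, ay, az = accel.sensor_triplet(opts.forearm_sensor)
    mag = magnitude(ax, ay, az, time=accel.time)
    events = detect_punches(mag, opts.detect_threshold_g, opts.min_separation_s)
    selected = select_best(events, opts.k_best)
    avg = average_event_magnitude(mag, selected, opts.avg_span_s)
    eop = end_of_punch(avg, opts.eop_search_window_s)
    end_times = [ev.peak_time + eop.offset_from_peak for ev in selected]

    envelopes: dict[tuple[str, str], EnvelopeSeries] = {}
    levels: dict[tuple[str, str], ActivationLevelSeries] = {}
    timings: list[MuscleTiming] = []
    for pos, entry in enumerate(cmap):
        chan = _emg_channel_for(emg, entry.channel_id, pos)
        segments = [
            extract_segment(chan, emg.time, t_end, opts.segment_duration_s, entry.key)
            for t_end in end_times
        ]
        rep = median_segments(segments)
        env, lev = process_segment(
            rep,
            band=opts.band_hz,
            band_order=opts.band_order,
            smooth_cutoff=opts.smooth_cutoff_hz,
            smooth_order=opts.smooth_order,
        )
        envelopes[entry.key] = env
        levels[entry.key] = lev
        onset = onset_time(env.normalized, env.time_rel, opts.onset_threshold, env.silent)
        mx = None if env.silent else max_activation_time(env.normalized, env.time_rel)
        timings.append(MuscleTiming(entry.side, entry.muscle, onset, mx))

    records, silent = build_sequence_table(timings, cmap)
    summary = summarize_peaks(selected)
    return SessionResult(
        events=events,
        selected=selected,
        eop=eop,
        end_times=end_times,
        avg_magnitude=avg,
        envelopes=envelopes,
        levels=levels,
        records=records,
        silent=silent,
        summary=summary,
    )


def write_results(result: SessionResult, out_dir: str | Path,
                  map_format: str = "png") -> dict[str, Path]:
    """Write sequence table (TSV), summary (JSON), events (JSON) and map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "sequence_table.tsv",
        "summary": out / "summary.json",
        "events": out / "events.json",
        "map": out / f"activation_map.{map_format}",
    }
    paths["table"].write_text(sequence_table_tsv(result.records))
    paths["summary"].write_text(result.summary.to_json())
    paths["events"].write_text(result.events_json())
    max_times = {
        (r.side, r.muscle): r.max_time for r in result.records
    }
    render_activation_map(
        [result.levels[key] for key in result.levels],
        paths["map"],
        max_times=max_times,
    )
    return paths
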