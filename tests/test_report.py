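"""Sequence table, peak summary statistics and the activation map."""

import numpy as np
import pytest

from emgseq import (
    MuscleTiming,
    build_sequence_table,
    default_channel_map,
    render_activation_map,
    summarize_peaks,
)
from emgseq.pipeline import ActivationLevelSeries
from emgseq.report import sequence_table_tsv


def _timings(onsets):
    return [MuscleTiming(s, m, on, on + 0.05 if on is not None else None)
            for (s, m), on in onsets.items()]


class TestBuildSequenceTable:
    def test_staggered_onsets_rank_in_construction_order(self):
        cmap = default_channel_map()
        onsets = {e.key: -0.48 + 0.02 * i for i, e in enumerate(cmap.entries)}
        records, silent = build_sequence_table(_timings(onsets), cmap)
        assert [r.sequence for r in records] == list(range(1, 17))
        assert [(r.side, r.muscle) for r in records] == [e.key for e in cmap]
        assert not silent

    def test_equal_onsets_tie_break_by_map_order(self):
        cmap = default_channel_map()
        onsets = {e.key: -0.2 for e in cmap.entries}
        records, _ = build_sequence_table(_timings(onsets), cmap)
        # stable-sort oracle on (onset, map position)
        oracle = sorted(onsets, key=lambda k: (onsets[k], cmap.order_of(*k)))
        assert [(r.side, r.muscle) for r in records] == oracle

    def test_single_muscle_table(self):
        cmap = default_channel_map()
        records, _ = build_sequence_table(
            [MuscleTiming("Right", "BB", -0.3, -0.2)], cmap
        )
        assert len(records) == 1
        assert records[0].sequence == 1

    def test_silent_muscles_listed_apart_not_ranked(self):
        cmap = default_channel_map()
        timings = [
            MuscleTiming("Right", "BB", -0.3, -0.2),
            MuscleTiming("Left", "BB", None, None),
        ]
        records, silent = build_sequence_table(timings, cmap)
        assert len(records) == 1
        assert [t.muscle for t in silent] == ["BB"]

    def test_all_missing_errors(self):
        cmap = default_channel_map()
        with pytest.raises(ValueError, match="missing"):
            build_sequence_table([MuscleTiming("Right", "BB", None, None)], cmap)

    def test_ranks_are_contiguous_permutation(self, rng):
        cmap = default_channel_map()
        onsets = {e.key: float(-rng.uniform(0.05, 0.45)) for e in cmap.entries}
        records, _ = build_sequence_table(_timings(onsets), cmap)
        assert sorted(r.sequence for r in records) == list(range(1, 17))
        assert [r.onset for r in records] == sorted(r.onset for r in records)


class TestSummarizePeaks:
    def test_identical_peaks_have_zero_sd(self):
        s = summarize_peaks([5.0] * 5)
        assert s.mean_peak == pytest.approx(5.0)
        assert s.sd_peak == pytest.approx(0.0)

    def test_two_values_sample_sd(self):
        s = summarize_peaks([1.0, 3.0])
        assert round(s.mean_peak, 2) == 2.00
        assert round(s.sd_peak, 2) == 1.41

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="no selected"):
            summarize_peaks([])

    def test_matches_two_pass_textbook_computation(self, rng):
        peaks = list(rng.uniform(20, 30, 9))
        s = summarize_peaks(peaks)
        mean = sum(peaks) / len(peaks)
        sd = (sum((p - mean) ** 2 for p in peaks) / (len(peaks) - 1)) ** 0.5
        assert s.mean_peak == pytest.approx(mean, abs=1e-12)
        assert s.sd_peak == pytest.approx(sd, abs=1e-12)

    def test_mean_within_peak_range(self, rng):
        peaks = list(rng.uniform(20, 30, 5))
        s = summarize_peaks(peaks)
        assert min(peaks) <= s.mean_peak <= max(peaks)


def _levels(n_muscles=16, n=200, fill=None, rng=None):
    t = (np.arange(n) - (n - 1)) / 2000
    out = []
    cmap = default_channel_map()
    for i, e in enumerate(cmap.entries[:n_muscles]):
        if fill is not None:
            lv = np.full(n, fill, dtype=np.int8)
        else:
            lv = (rng.integers(0, 4, n)).astype(np.int8)
        out.append(ActivationLevelSeries(muscle=e.key, time_rel=t, levels=lv))
    return out


class TestRenderActivationMap:
    def test_png_created_with_16_rows(self, tmp_path, rng):
        path = render_activation_map(_levels(rng=rng), tmp_path / "map.png")
        assert path.exists() and path.stat().st_size > 0

    def test_all_zero_levels_render(self, tmp_path):
        path = render_activation_map(_levels(fill=0), tmp_path / "map.png")
        assert path.exists()

    def test_svg_output_is_deterministic(self, tmp_path):
        levels = _levels(n_muscles=4, fill=2)
        mt = {s.muscle: -0.02 for s in levels}
        p1 = render_activation_map(levels, tmp_path / "a.svg", max_times=mt)
        p2 = render_activation_map(levels, tmp_path / "b.svg", max_times=mt)
        assert p1.read_bytes() == p2.read_bytes()

    def test_mismatched_time_axes_rejected(self, tmp_path):
        bad = _levels(n_muscles=2, fill=1)
        bad[1].time_rel = bad[1].time_rel + 1.0
        with pytest.raises(ValueError, match="time axis"):
            render_activation_map(bad, tmp_path / "map.png")


def test_sequence_table_tsv_layout():
    cmap = default_channel_map()
    records, _ = build_sequence_table(
        [MuscleTiming("Left", "RF", -0.308, -0.25)], cmap
    )
    tsv = sequence_table_tsv(records)
    lines = tsv.strip().split("\n")
    assert lines[0].split("\t") == ["sequence", "side", "muscle", "onset_s", "max_s"]
    assert lines[1].split("\t") == ["1", "Left", "RF", "-0.308", "-0.250"]
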