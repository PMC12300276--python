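# emgseq

Muscle-activation sequencing from surface EMG and accelerometer recordings
of explosive movements, built around the karate reverse punch (Gyaku
Tsuki).

A fast strike recruits leg, trunk and arm muscles in a fixed order within
about a third of a second.  `emgseq` quantifies that order and its timing
from an instrumented session — 16 wireless sEMG sensors (2000 Hz) with
integrated tri-axial accelerometers (142 Hz) — for biomechanics
researchers and coaches analysing technique.

## Method

1. **Events.** The punching forearm's acceleration magnitude
   `|a| = sqrt(ax² + ay² + az²)` (in g) is scanned for supra-threshold
   excursions; the 5 punches (of ~20) with the largest peaks are kept.
   The *end of punch* (time 0) is the minimum of the peak-aligned,
   trial-averaged `|a|` shortly after the peak — the maximal deceleration
   at impact.
2. **Envelope.** Per muscle, the pointwise **median** of the 0.5 s EMG
   segments ending at the end-of-punch is band-passed (30–300 Hz,
   order-6 Butterworth, zero-phase), transformed with the
   **Teager–Kaiser energy operator** `Ψ(xₙ) = xₙ² − xₙ₊₁·xₙ₋₁`,
   low-passed (7 Hz, order 4, zero-phase) and min–max normalized to
   [0, 1].
3. **Levels and sequence.** The normalized envelope is discretized into
   activation levels 0–3 at 0.25/0.5/0.75; **onset** is the first sample
   ≥ 0.25 (the level 0→1 transition) and muscles are ranked by onset.
   The result is an ordered sequence table, peak summary statistics
   (mean ± sample SD of the selected peaks) and an activation-map figure
   (one row per muscle, darker = higher level, white marker at maximal
   activation).

Every result is invariant to rescaling a raw EMG channel (TKEO scales
quadratically, normalization cancels it), so electrode gain never matters.

A synthetic-session generator (`emgseq.synthetic`) produces EMG +
accelerometer bundles with known impact times, burst onsets and peak
magnitudes, and is how the pipeline is validated end to end.

## Worked example

```sh
$ emgseq simulate --n-punches 20 --seed 1 --out-dir session
$ emgseq analyze --emg session/emg.tsv --accel session/accel.tsv --out-dir results
20 punches detected, best 5 kept (mean 25.13 g, SD 0.97 g)
   1  Left  RF   onset -0.285 s  max -0.218 s
   2  Right BB   onset -0.268 s  max -0.200 s
   3  Left  MG   onset -0.256 s  max -0.191 s
   ...
  16  Right ECR  onset -0.081 s  max +0.000 s
wrote results/sequence_table.tsv
wrote results/summary.json
wrote results/events.json
wrote results/activation_map.png
```

The five best punches averaged 25.13 g at the peak.  Onsets are seconds
*before* impact: the front-leg rectus femoris fires first (−0.285 s) to
stabilise the stance, and the wrist stabiliser (extensor carpi radialis)
of the punching arm last (−0.081 s) — the whole chain fires inside
~0.2 s.  The same analysis is available from Python via
`emgseq.analyze_session`; the scripts in `examples/` walk through each
stage (simulation, event detection, envelope processing, full analysis)
with commented output.

Input tables are delimited text (tab/semicolon/comma, decimal comma
tolerated) with a leading time or sample-index column; the channel map
(which electrode sits on which muscle) is YAML/JSON, with a built-in
default for the standard 16-electrode layout (8 muscles × 2 sides: MG,
RF, EO, PM, AD, BB, LT, ECR).

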