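# Methods

## The problem

In explosive striking techniques such as the karate reverse punch, a chain
of leg, trunk and arm muscles fires within roughly a third of a second.
Quantifying *which* muscle activates *when* requires (a) a reproducible
per-trial time reference, (b) an EMG envelope whose onset is not biased by
filter delay, and (c) a representation that is invariant to electrode gain
and skin impedance.  `emgseq` implements one complete solution: the impact
landmark comes from the punching forearm's accelerometer, the envelope
from a Teager-Kaiser energy transform, and the activation measure from a
per-muscle min-max normalized, quartile-discretized envelope.

## Event detection and the time reference

The forearm acceleration magnitude

    |a|(t) = sqrt(ax^2 + ay^2 + az^2)      [multiples of g]

spikes to tens of g as the fist accelerates and dips sharply as it
decelerates against the target.  Punches are detected as supra-threshold
excursions of |a| (default threshold 5 g, minimum peak separation 2 s;
both sit an order of magnitude away from the ~25 g peaks at ~5 s spacing
they segment, so their exact values are uncritical).  The `k` punches with
the largest peak magnitude (default 5) are retained — maximal peak
acceleration is used as the proxy for strike quality.

The *end of punch* — time zero of all activation times — is the global
minimum of |a| in a post-peak window (default 0.3 s) of the **trial-averaged**
magnitude, aligned at each trial's peak.  Averaging before taking the
minimum suppresses single-trial noise in the flat dip region; the common
peak-to-minimum offset is then transferred back to each selected trial
(per-trial end = trial peak time + offset).  Alignment at the peak is used
because the peak is the only per-trial landmark available before the
minimum is known.  The minimum is taken on the magnitude rather than a
signed axis (the magnitude is orientation-invariant and is the signal used
for selection); a signed-axis variant can be obtained by passing a
single-axis bundle.  Ties (equal minima, equal peaks at the selection cut)
resolve to the earlier time, for determinism.

Accelerometer (142 Hz) and EMG (2000 Hz) timelines are linked by
nearest-sample mapping; at 7 ms accelerometer resolution, sub-sample
interpolation would suggest spurious precision.

## The EMG envelope

For each muscle, 0.5 s segments ending at the per-trial end-of-punch are
cut from the raw EMG and combined by **pointwise median** across the
selected trials — robust to a single aberrant trial in a way the mean is
not.  The median segment is then processed:

1. **Band-pass** 30–300 Hz, Butterworth, overall order 6 (three
   second-order sections), applied zero-phase (forward–backward).  The
   published description of the filter does not fix the convention for
   "order" of a band-pass; this package reads it as the overall order.
   Zero-phase application doubles effective attenuation and, crucially,
   introduces no group delay that would bias onset times.
2. **TKEO**: Ψ(xₙ) = xₙ² − xₙ₊₁·xₙ₋₁.  For a sinusoid A·sin(ωn) this
   yields the constant A²·sin²ω, so the operator rewards both amplitude
   and frequency and sharpens burst/background contrast for onset
   detection.  The first and last sample, where the operator is
   undefined, copy their nearest interior value (length is preserved
   without fabricating energy).
3. **Smoothing**: 7 Hz order-4 Butterworth low-pass, zero-phase.
4. **Normalization**: min–max to [0, 1] over the segment's own smoothed
   envelope.  Combined with the TKEO's quadratic scaling this makes every
   downstream quantity invariant to multiplying the raw channel by any
   a > 0 — EMG amplitude units are treated as arbitrary throughout.
   Max-only scaling (x/max) is available via `normalize01` replacement but
   min–max is the default: it guarantees the full [0, 1] range that the
   level thresholds presuppose.
5. **Discretization** into activation levels 0–3 at 0.25 / 0.5 / 0.75
   (level 1 = [0.25, 0.5), level 3 = [0.75, 1]).

**Onset** is the first sample with normalized amplitude ≥ 0.25 —
implemented with the closed left boundary so that onset coincides exactly
with the level-0→1 transition of the discretized series.  **Maximal
activation** is the argmax (earliest index on ties).  Muscles are ranked
ascending by onset; exact onset ties break by channel-map order.  A
constant (silent) envelope — min–max range below 1e-12 — normalizes to all
zeros, is flagged, and is listed separately without a rank rather than
being assigned a fictitious onset.

### Numerical choices

- Zero-phase filtering of short segments needs edge handling: segments are
  reflection-padded before filtering and cropped after.  The default pad
  is 0.3 s: the slowest band-pass pole (|p| ≈ 0.959 at 2000 Hz) needs
  ~660 samples to decay below 1e-12, so a 0.3 s (600-sample) pad keeps
  edge transients at the ~1e-12 level (a 0.1 s pad leaves ~1e-4 relative
  error and measurably breaks time-reversal symmetry of the filter).
- `extract_segment` takes the sample at or nearest before the requested
  end time; the relative axis ends at exactly 0 and a 0.5 s window at
  2000 Hz is exactly 1000 samples.
- The sampling-rate check on file input tolerates 1 % relative jitter in
  the time column by default.

## The synthetic generator

`synthetic.simulate_session` emulates the recording protocol end to end:
20 punches at 5 s nominal intervals (±0.15 s uniform jitter, snapped to
the accelerometer grid so constructed peaks are attained by samples), a
3 s lead-in, EMG at 2000 Hz, accelerometer at 142 Hz.

- **Accelerometer**: magnitude baseline 1 g; per punch a half-sine peak
  (60 ms wide, amplitude 23 ± 1.5 g across punches) followed 0.08 s later
  by a V-shaped dip to 0.15 g at impact, plus ~0.02–0.03 g axis noise.
  The ~23 g mean with 1.5 g spread puts the maximum of 20 draws near 26 g,
  matching the scale of elite-level strikes.
- **EMG**: per channel, background band-limited noise (white noise
  band-passed 30–300 Hz, the spectral band the pipeline analyses) of
  amplitude 1/SNR, plus per-punch bursts: the same kind of carrier noise
  under a Gaussian amplitude envelope (σ = duration/5, support trimmed to
  [onset, onset + duration]).  Defaults: burst duration 0.18 s, SNR 10.
- **Default onsets** are a measured activation sequence of a right-handed
  reverse punch (16 muscles, −0.308 s to −0.110 s relative to impact), so
  the generator's ground truth reproduces a realistic inter-muscle
  pattern, including near-simultaneous pairs a few ms apart.

The burst duration and shape were set so the generator honours its
contract with the detector: with a Gaussian rise, the smoothed envelope
crosses 0.25 of its maximum 10–40 ms *after* the true onset.  A much
sharper rise (≲ 60 ms burst) interacts with the zero-phase 7 Hz smoother,
whose impulse response spreads symmetrically ±~40 ms, and can push the
crossing slightly *before* the true onset; 0.15–0.2 s is also the
physiologically sensible burst span for a movement that completes in
~0.3 s.  The onset-timing jitter of the full pipeline on default-SNR
synthetic data has a standard deviation of ~6 ms (dominated by the
stochastic burst carrier, not the additive noise), which is why true onset
differences of 1–8 ms — present in the measured sequence — are below the
method's resolving power, while 20–30 ms separations are recovered
reliably.

What the generator does *not* model: motor-unit recruitment and firing
statistics, movement artefacts, electrode crosstalk between neighbouring
muscles, baseline drift, power-line interference, and inter-trial
variability of the activation pattern itself (every punch uses the same
true offsets).  Passing the recovery tests therefore shows the pipeline's
correctness and timing behaviour under its stated signal model, not its
robustness to every artefact of real recordings.

## Sequence-recovery experiments

Two seeded experiments quantify recovery (run by the test suite and
`scripts/acceptance.py`):

1. **Staggered order**: 16 onsets spaced exactly 30 ms apart.  Sixteen
   such onsets span 450 ms, which cannot fit, with any realistic burst
   duration, inside the default 0.5 s pre-impact window — bursts of the
   latest muscles would be truncated at the segment edge, degrading their
   normalization and detection.  The experiment therefore analyses an
   0.8 s window (all other parameters default), placing onsets from
   −0.75 s in 30 ms steps.  The constructed order is recovered, with every
   onset inside [t₀, t₀ + 50 ms], in ≥ 95 % of seeds.
2. **Single burst**: one muscle, true onset −0.25 s, default 0.5 s window;
   the detected onset falls in [t₀, t₀ + 50 ms] in ≥ 95 % of seeds
   (typical lag 12–35 ms).

Recovery experiments use 8- or 6-punch sessions: the invariants under test
concern the segments of the best five trials, so additional punches add
runtime without adding information.

## Known limitations

- The onset definition (first 0.25 crossing of a per-segment min–max
  normalized envelope) reports onsets *relative to that muscle's own
  dynamic range* in the analysed window; a muscle with substantial tonic
  activity before the window will look different from one starting from
  silence.
- Detected onsets carry a systematic positive lag (the envelope must rise
  to a quarter of its maximum), so absolute onset times are comparable
  within a session but depend on burst morphology.
- The impact minimum assumes the characteristic peak-then-dip morphology
  of a strike against a target; movements without a sharp deceleration
  have no well-defined end-of-punch.
- Silent-channel handling, tie rules and boundary conventions are chosen
  for determinism and are documented above; alternative conventions would
  shift onsets by at most one sample.
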