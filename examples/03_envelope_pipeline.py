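"""Process one muscle's EMG segment into activation levels.

Stages: median of the best-trial segments -> 30-300 Hz band-pass ->
Teager-Kaiser energy operator -> 7 Hz low-pass envelope -> min-max
normalization -> quartile discretization (levels 0-3).  Onset is the
first instant the normalized envelope reaches 0.25.
"""

import numpy as np

from emgseq import (
    SimConfig,
    extract_segment,
    max_activation_time,
    median_segments,
    onset_time,
    process_segment,
    simulate_session,
)

emg, accel, truth = simulate_session(SimConfig(n_punches=8, seed=1))

# Use the constructed truth for the segment ends (the full pipeline derives
# them from the accelerometer; see 04_full_analysis.py).
muscle = ("Right", "AD")
chan = emg.channel("ch9_Right_AD")
ends = truth.impact_times[:5]

segments = [extract_segment(chan, emg.time, t, duration=0.5, muscle=muscle)
            for t in ends]
rep = median_segments(segments)
env, levels = process_segment(rep)

onset = onset_time(env.normalized, env.time_rel)
peak = max_activation_time(env.normalized, env.time_rel)
true_onset = truth.onset_offsets[muscle]

print(f"muscle              : {muscle[0]} {muscle[1]}")
print(f"segment             : {len(rep.samples)} samples "
      f"({rep.time_rel[0]:.3f} .. {rep.time_rel[-1]:.3f} s)")
print(f"true burst onset    : {true_onset:+.3f} s")
print(f"detected onset      : {onset:+.3f} s (first 0.25 crossing)")
print(f"maximal activation  : {peak:+.3f} s")
counts = {lv: int(np.sum(levels.levels == lv)) for lv in range(4)}
print(f"samples per level   : {counts}")
print("Detection trails the true onset by a few tens of ms because the")
print("envelope must rise to a quarter of its maximum before it counts.")
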