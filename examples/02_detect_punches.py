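"""Detect punch events on the forearm accelerometer and select the best.

The acceleration magnitude |a| = sqrt(ax^2 + ay^2 + az^2) spikes to tens
of g at each punch; the five punches with the largest peaks are kept, and
the trial-averaged magnitude locates the impact minimum (end of punch)
that defines time zero for the EMG analysis.
"""

from emgseq import (
    SimConfig,
    average_event_magnitude,
    detect_punches,
    end_of_punch,
    magnitude,
    select_best,
    simulate_session,
)

emg, accel, truth = simulate_session(SimConfig(seed=1))

ax, ay, az = accel.sensor_triplet(0)
mag = magnitude(ax, ay, az, time=accel.time)

events = detect_punches(mag, threshold=5.0, min_separation=2.0)
best = select_best(events, k=5)
avg = average_event_magnitude(mag, best, span=(0.5, 0.5))
eop = end_of_punch(avg, search_window=0.3)

print(f"detected punches : {len(events)} (simulated: {len(truth.impact_times)})")
print(f"best five peaks  : {sorted(round(e.peak_mag, 2) for e in best)} g")
print(f"impact minimum   : {eop.offset_from_peak * 1000:.1f} ms after the peak")
print("Per punch, end-of-punch = peak time + that common offset; EMG")
print("segments are cut to end exactly there.")
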