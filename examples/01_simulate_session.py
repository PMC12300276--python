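"""Generate a synthetic punching session and inspect its ground truth.

The generator emulates an instrumented session: 20 reverse punches at ~5 s
intervals, 16 EMG channels (2000 Hz) with per-muscle activation bursts,
and the punching forearm's tri-axial accelerometer (142 Hz) showing a
~25 g peak then a sharp deceleration dip at each impact.
"""

from emgseq import SimConfig, simulate_session

cfg = SimConfig(seed=1)
emg, accel, truth = simulate_session(cfg)

print(f"session length      : {emg.duration:.1f} s")
print(f"EMG channels        : {emg.n_channels} at {emg.sampling_rate:.0f} Hz")
print(f"accel channels      : {accel.n_channels} at {accel.sampling_rate:.0f} Hz")
print(f"punches             : {len(truth.impact_times)}")
print(f"first impacts (s)   : {[round(float(t), 2) for t in truth.impact_times[:5]]}")
print(f"peak magnitudes (g) : {[round(float(m), 1) for m in truth.peak_mags[:5]]} ...")

# Each muscle's burst starts at a fixed offset before impact; these offsets
# are the ground truth the analysis pipeline should recover.
first = min(truth.onset_offsets, key=truth.onset_offsets.get)
last = max(truth.onset_offsets, key=truth.onset_offsets.get)
print(f"earliest muscle     : {first} at {truth.onset_offsets[first]} s")
print(f"latest muscle       : {last} at {truth.onset_offsets[last]} s")
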