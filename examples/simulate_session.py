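"""Simulate one screening recording and inspect its structure.

Builds a subject whose evoked responses are strongest at 5 and 9 Hz,
simulates the four-frequency screening step (15 repetitions of each
flicker class plus rest, 3 s events) and prints the recording layout.
"""

from vibci import make_subject_profile, simulate_recording
from vibci.simulate import ProtocolSpec

profile = make_subject_profile(seed=3, config={
    "gains": {5: 4.0, 9: 4.0, 7: 2.0, 12: 2.0},
})
protocol = ProtocolSpec.step_1()
rec = simulate_recording(protocol, profile, seed=11, fs=256.0,
                         recording_id="screening")

print(f"channels : {', '.join(rec.channel_labels)}")
print(f"duration : {rec.duration:.0f} s at {rec.fs:g} Hz")
print(f"events   : {len(rec.annotations)} "
      f"({protocol.reps_per_class} per class x {len(protocol.classes)} classes)")
print("first 5  :", [a.label for a in rec.annotations[:5]])

# Each event is 3 s of background EEG plus, for flicker classes, a
# sinusoid at the class frequency and a weaker one at its second
# harmonic, largest over the occipital electrodes.
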