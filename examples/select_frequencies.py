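"""Select a subject's flicker-frequency couple from screening data.

Runs the full selection chain on a simulated screening session: filter
chain, 1-s epochs from 1.8-2.8 s of each event, high-resolution PSDs
over Oz/O1/O2, the peak score S = max(dp+, dp-)/iota at each candidate
frequency and its second harmonic, and the top-two couple.
"""

from vibci import make_subject_profile, simulate_recording
from vibci.freq_select import score_candidates, select_couple
from vibci.preprocess import extract_epochs, filter_chain
from vibci.simulate import ProtocolSpec

profile = make_subject_profile(seed=3, config={
    "gains": {5: 4.0, 9: 4.0, 7: 2.0, 12: 2.0},
})
protocol = ProtocolSpec.step_1()
rec = simulate_recording(protocol, profile, seed=11, fs=256.0)
epochs = extract_epochs(filter_chain(rec), protocol)

table = score_candidates(epochs)
couple = select_couple(table)

print("candidate frequency scores (summed over 15 reps x 3 occipital"
      " electrodes x {f, 2f}):")
for f, total in sorted(table.items()):
    marker = " <-- selected" if f in (couple.f_low, couple.f_high) else ""
    print(f"  {f:4.0f} Hz : {total:10.1f}{marker}")
print(f"selected couple: ({couple.f_low:g} Hz, {couple.f_high:g} Hz)")
# Higher scores mean taller, narrower PSD peaks at the stimulation
# frequency; the planted 5/9 Hz responses should win.
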