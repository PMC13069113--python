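"""Decode imagery classes offline with temporal cross-validation.

Simulates the ten offline imagery recordings of one subject (two
imagery classes plus rest, 20 x 9 s events each), builds Welch-PSD
features (10 electrodes x 67 bins over 3-36 Hz) and runs the 5-fold
temporal cross-validation: each fold tests on a consecutive pair of
recordings and trains the linear SVM on the other eight.
"""

from vibci import (
    build_features,
    extract_epochs,
    filter_chain,
    imagery_label,
    make_subject_profile,
    simulate_recording,
    temporal_cv,
)
from vibci.recording import REST_LABEL
from vibci.simulate import ProtocolSpec

COUPLE = (5.0, 9.0)
profile = make_subject_profile(seed=7, config={"gains": {5: 4.0, 9: 4.0}})
protocol = ProtocolSpec.step_3(COUPLE)

blocks = []
for i in range(10):
    rec = simulate_recording(protocol, profile, couple=COUPLE,
                             seed=100 + i, fs=256.0,
                             recording_id=f"offline_{i:02d}")
    blocks.append(build_features(extract_epochs(filter_chain(rec), protocol)))

order = [imagery_label(COUPLE[0]), REST_LABEL, imagery_label(COUPLE[1])]
cv = temporal_cv(blocks, class_order=order)

print("fold accuracies (%):",
      [f"{a:.1f}" for a in cv.fold_accuracies])
print(f"mean +- sd : {cv.mean_accuracy:.2f} +- {cv.std_accuracy:.2f} %")
print(f"best fold  : {cv.best_fold} "
      "(its model would drive the online session)")
# Accuracy well above the ~33% 3-class chance level reflects the
# imagery peaks at 5 and 9 Hz that separate the three classes.
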