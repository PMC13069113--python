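"""Core containers for continuous EEG and task-locked epochs.

A recording is a plain channels x samples array in microvolts with a
sampling rate and a list of non-overlapping task annotations.  The fixed
analysis montage is the 10-electrode subset used for classification;
``OCCIPITAL_CHANNELS`` is the subset the frequency-selection score reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: The 10-20 electrodes entering classification, in fixed feature order.
ANALYSIS_CHANNELS: tuple[str, ...] = (
    "O2", "O1", "Pz", "P3", "P4", "Oz", "T7", "P7", "AF4", "F8",
)

#: Electrodes over the occipital cortex used for SSVEP peak scoring.
OCCIPITAL_CHANNELS: tuple[str, ...] = ("Oz", "O1", "O2")

#: The candidate flicker frequencies (Hz) shown / imagined by subjects.
CANDIDATE_FREQS: tuple[float, ...] = (5.0, 7.0, 9.0, 12.0)

#: Class label for the rest state.
REST_LABEL = "rest"


def perception_label(freq: float) -> str:
    """Class label for an actually-viewed flicker at ``freq`` Hz."""
    return f"vp_{freq:g}"


def imagery_label(freq: float) -> str:
    """Class label for an imagined flicker at ``freq`` Hz."""
    return f"vi_{freq:g}"


def label_frequency(label: str) -> float | None:
    """Flicker frequency encoded in a class label, or None for rest."""
    if label == REST_LABEL:
        return None
    kind, _, freq = label.partition("_")
    if kind not in ("vp", "vi") or not freq:
        raise ValueError(f"unrecognised class label {label!r}")
    return float(freq)


def is_imagery_label(label: str) -> bool:
    return label.startswith("vi_")


@dataclass(frozen=True)
class Annotation:
    """One task event: onset and duration in seconds, class label."""

    onset: float
    duration: float
    label: str

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("annotation duration must be positive")
        if self.onset < 0:
            raise ValueError("annotation onset must be non-negative")


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts with event annotations."""

    channel_labels: tuple[str, ...]
    fs: float
    data: np.ndarray  # (n_channels, n_samples), µV
    annotations: list[Annotation] = field(default_factory=list)
    recording_id: str = ""

    def __post_init__(self):
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} channel labels but "
                f"{self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.validate_annotations()

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def validate_annotations(self) -> None:
        """Annotations must be sorted, non-overlapping and in-span."""
        prev_end = -math.inf
        for ann in self.annotations:
            if ann.onset < prev_end - 1e-9:
                raise ValueError(
                    f"annotation at {ann.onset:.3f}s overlaps the previous event"
                )
            if ann.onset + ann.duration > self.duration + 1e-9:
                raise ValueError(
                    f"annotation {ann.label!r} at {ann.onset:.3f}s extends past "
                    f"the end of the recording ({self.duration:.3f}s)"
                )
            prev_end = ann.onset + ann.duration

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]


@dataclass
class Epoch:
    """One task's channels x samples slice, windowed relative to event onset."""

    label: str
    data: np.ndarray  # (n_channels, n_samples), µV
    window: tuple[float, float]  # [start, end) seconds from event onset
    fs: float
    channel_labels: tuple[str, ...]
    step_id: int
    recording_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        start, end = self.window
        expected = round((end - start) * self.fs)
        if self.data.shape != (len(self.channel_labels), expected):
            raise ValueError(
                f"epoch data shape {self.data.shape} inconsistent with window "
                f"[{start}, {end}) at fs={self.fs}"
            )

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epoch") from None
        return self.data[idx]
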