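"""Synthetic EEG sessions for the four-step flicker-imagery protocol.

The generator emulates what the analysis pipeline actually consumes: a
1/f-type Gaussian background per electrode plus, during task events,
narrowband oscillations at the flicker frequency and its second harmonic.
Imagery events are attenuated copies of the evoked ones with a small
per-event frequency offset, reproducing the lower, broader spectral peaks
seen when a stimulus is imagined rather than viewed.

Protocol presets follow the experimental design: Step 1 is an evoked
(SSVEP) screening over all four candidate frequencies, Step 2 a mixed
familiarization session, Step 3 the offline imagery session (ten
recordings feed the classifier) and Step 4 the fixed-sequence online
imagery session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import (
    ANALYSIS_CHANNELS,
    CANDIDATE_FREQS,
    REST_LABEL,
    Annotation,
    EEGRecording,
    imagery_label,
    is_imagery_label,
    label_frequency,
    perception_label,
)

#: Default sampling rate (Hz); typical for research-grade EEG amplifiers.
DEFAULT_FS = 256.0

#: Band over which the background RMS amplitude is defined (Hz).  Pinning
#: the noise amplitude to a fixed band keeps signal-to-noise independent
#: of the sampling rate.
NOISE_REFERENCE_BAND = (1.0, 40.0)

#: Per-channel spatial gain of the visual response: strongest over the
#: occipital cortex, weaker parietally, weakest at temporal/frontal sites.
DEFAULT_SPATIAL_GAIN: dict[str, float] = {
    "O2": 1.0, "O1": 1.0, "Oz": 1.0,
    "Pz": 0.6, "P3": 0.6, "P4": 0.6, "P7": 0.6,
    "T7": 0.35, "AF4": 0.35, "F8": 0.35,
}

#: Default profile configuration.  Amplitudes in µV: evoked occipital
#: responses of a few microvolts over a ~10 µV broadband background.
DEFAULT_PROFILE_CONFIG: dict = {
    "gain_range": (2.0, 4.0),   # µV, uniform draw per candidate frequency
    "gains": None,               # explicit {freq: µV} overrides the draw
    "harmonic_ratio": 0.3,       # 2f amplitude relative to f
    "spatial_gain": None,        # {channel: gain}; default montage profile
    "vi_attenuation": 0.5,       # imagery amplitude relative to perception
    "vi_jitter_sd": 0.1,         # Hz, per-event imagery frequency smear
    "noise_exponent": 1.0,       # 1/f^alpha spectral slope
    "noise_scale": 10.0,         # µV RMS in NOISE_REFERENCE_BAND
}


@dataclass(frozen=True)
class SubjectProfile:
    """Response structure of one simulated subject.

    ``response_gain`` maps each candidate flicker frequency to the µV
    amplitude of the fundamental oscillation at unit spatial gain.
    """

    response_gain: dict[float, float]
    harmonic_ratio: float
    spatial_gain: dict[str, float]
    vi_attenuation: float
    vi_jitter_sd: float
    noise_exponent: float
    noise_scale: float
    seed: int

    def __post_init__(self):
        for f, g in self.response_gain.items():
            if f not in CANDIDATE_FREQS:
                raise ValueError(f"response gain for non-candidate frequency {f}")
            if g < 0:
                raise ValueError("response gains must be non-negative")
        if not 0 <= self.harmonic_ratio <= 1:
            raise ValueError("harmonic_ratio must be in [0, 1]")
        if not 0 < self.vi_attenuation <= 1:
            raise ValueError("vi_attenuation must be in (0, 1]")
        if self.vi_jitter_sd < 0:
            raise ValueError("vi_jitter_sd must be non-negative")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if any(g < 0 for g in self.spatial_gain.values()):
            raise ValueError("spatial gains must be non-negative")


def make_subject_profile(seed: int, config: dict | None = None) -> SubjectProfile:
    """Draw a reproducible subject profile from a configuration map.

    Unknown keys are rejected; per-frequency gains are drawn uniformly
    from ``gain_range`` unless ``gains`` pins them explicitly.  The same
    (seed, config) pair always yields an identical profile.
    """
    cfg = dict(DEFAULT_PROFILE_CONFIG)
    for key, value in (config or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown profile config key {key!r}")
        cfg[key] = value

    lo, hi = cfg["gain_range"]
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid gain range ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    draws = rng.uniform(lo, hi, size=len(CANDIDATE_FREQS))
    gains = {f: float(g) for f, g in zip(CANDIDATE_FREQS, draws)}
    if cfg["gains"] is not None:
        for f, g in cfg["gains"].items():
            gains[float(f)] = float(g)

    spatial = dict(DEFAULT_SPATIAL_GAIN if cfg["spatial_gain"] is None
                   else cfg["spatial_gain"])
    return SubjectProfile(
        response_gain=gains,
        harmonic_ratio=float(cfg["harmonic_ratio"]),
        spatial_gain=spatial,
        vi_attenuation=float(cfg["vi_attenuation"]),
        vi_jitter_sd=float(cfg["vi_jitter_sd"]),
        noise_exponent=float(cfg["noise_exponent"]),
        noise_scale=float(cfg["noise_scale"]),
        seed=int(seed),
    )


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and class layout of one protocol step."""

    step_id: int
    classes: tuple[str, ...]
    reps_per_class: int
    event_duration: float  # seconds
    epoch_window: tuple[float, float]  # [start, end) s from event onset
    sequence_mode: str = "randomized"  # or "fixed"
    blocks: int = 1

    def __post_init__(self):
        if self.sequence_mode not in ("randomized", "fixed"):
            raise ValueError(f"unknown sequence mode {self.sequence_mode!r}")
        start, end = self.epoch_window
        if not 0 <= start < end:
            raise ValueError("epoch window must satisfy 0 <= start < end")
        if end > self.event_duration + 1e-9:
            raise ValueError("epoch window must fit inside the event duration")

    @property
    def n_events(self) -> int:
        return len(self.classes) * self.reps_per_class * self.blocks

    # -- presets -------------------------------------------------------

    @staticmethod
    def step_1() -> "ProtocolSpec":
        """Evoked screening: four flicker classes plus rest, 15 x 3 s."""
        classes = tuple(perception_label(f) for f in CANDIDATE_FREQS) + (REST_LABEL,)
        return ProtocolSpec(1, classes, reps_per_class=15, event_duration=3.0,
                            epoch_window=(1.8, 2.8))

    @staticmethod
    def step_2(couple: "tuple[float, float]") -> "ProtocolSpec":
        """Mixed evoked/imagery familiarization at the selected couple."""
        lo, hi = _couple_pair(couple)
        classes = (perception_label(lo), imagery_label(lo), REST_LABEL,
                   perception_label(hi), imagery_label(hi))
        return ProtocolSpec(2, classes, reps_per_class=18, event_duration=3.0,
                            epoch_window=(1.8, 2.8), blocks=3)

    @staticmethod
    def step_3(couple: "tuple[float, float]") -> "ProtocolSpec":
        """Offline imagery session: two imagery classes plus rest, 20 x 9 s."""
        lo, hi = _couple_pair(couple)
        classes = (imagery_label(lo), REST_LABEL, imagery_label(hi))
        return ProtocolSpec(3, classes, reps_per_class=20, event_duration=9.0,
                            epoch_window=(1.0, 7.0))

    @staticmethod
    def step_4(couple: "tuple[float, float]") -> "ProtocolSpec":
        """Online imagery session: fixed lower/rest/higher sequence, 20 x 5 s."""
        lo, hi = _couple_pair(couple)
        classes = (imagery_label(lo), REST_LABEL, imagery_label(hi))
        return ProtocolSpec(4, classes, reps_per_class=20, event_duration=5.0,
                            epoch_window=(1.0, 4.0), sequence_mode="fixed")


def _couple_pair(couple) -> tuple[float, float]:
    lo, hi = float(couple[0]), float(couple[1])
    if not lo < hi:
        raise ValueError("frequency couple must be ordered (low, high)")
    return lo, hi


def _event_sequence(protocol: ProtocolSpec, rng: np.random.Generator) -> list[str]:
    if protocol.sequence_mode == "fixed":
        # The online sequence cycles through the classes in protocol order.
        return list(protocol.classes) * (protocol.reps_per_class * protocol.blocks)
    sequence: list[str] = []
    for _ in range(protocol.blocks):
        block = [c for c in protocol.classes for _ in range(protocol.reps_per_class)]
        rng.shuffle(block)
        sequence.extend(block)
    return sequence


def _pink_background(n_samples: int, fs: float, exponent: float, scale_uv: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^alpha noise with ``scale_uv`` RMS in the reference band."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    coeffs = shape * (rng.standard_normal(len(freqs))
                      + 1j * rng.standard_normal(len(freqs)))
    coeffs[0] = 0.0
    lo, hi = NOISE_REFERENCE_BAND
    band = (freqs >= lo) & (freqs <= hi)
    # Parseval for the real inverse FFT: mean square of the band-limited
    # component is 2 * sum |X_k|^2 / n^2 over the band's positive bins.
    band_rms = np.sqrt(2.0 * np.sum(np.abs(coeffs[band]) ** 2)) / n_samples
    if band_rms > 0 and scale_uv > 0:
        coeffs *= scale_uv / band_rms
    elif scale_uv == 0:
        coeffs[:] = 0.0
    return np.fft.irfft(coeffs, n=n_samples)


def simulate_recording(protocol: ProtocolSpec, profile: SubjectProfile,
                       couple: tuple[float, float] | None = None,
                       seed: int = 0, fs: float = DEFAULT_FS,
                       channel_labels: tuple[str, ...] = ANALYSIS_CHANNELS,
                       recording_id: str = "") -> EEGRecording:
    """Simulate one annotated recording of a protocol step.

    Each task event adds, on top of the continuous background, a sinusoid
    at the class frequency and one at its second harmonic (scaled by the
    profile's harmonic ratio), both multiplied by the per-channel spatial
    gain; imagery events are further attenuated and frequency-jittered.
    Rest events carry background only.  Identical arguments produce an
    identical recording.
    """
    if protocol.step_id == 1:
        if couple is not None:
            raise ValueError("Step 1 uses all four candidates; pass couple=None")
    elif couple is None:
        raise ValueError(f"Step {protocol.step_id} requires a frequency couple")

    used_freqs = {label_frequency(c) for c in protocol.classes} - {None}
    for f in used_freqs:
        if f not in profile.response_gain:
            raise ValueError(f"unknown class frequency {f} Hz: not in profile")
    max_component = 2.0 * max(used_freqs, default=0.0)
    if fs <= 2.0 * max_component:
        raise ValueError(
            f"fs={fs} Hz too low for the {max_component} Hz second harmonic"
        )

    rng = np.random.default_rng(seed)
    sequence = _event_sequence(protocol, rng)
    samples_per_event = round(protocol.event_duration * fs)
    n_samples = samples_per_event * len(sequence)

    gains = np.array([profile.spatial_gain.get(ch, 1.0) for ch in channel_labels])
    data = np.empty((len(channel_labels), n_samples))
    for ch in range(len(channel_labels)):
        data[ch] = gains[ch] * _pink_background(
            n_samples, fs, profile.noise_exponent, profile.noise_scale, rng)

    annotations: list[Annotation] = []
    t_event = np.arange(samples_per_event) / fs
    for i, label in enumerate(sequence):
        onset = i * protocol.event_duration
        annotations.append(Annotation(onset, protocol.event_duration, label))
        f0 = label_frequency(label)
        if f0 is None:
            continue
        amp = profile.response_gain[f0]
        if is_imagery_label(label):
            amp *= profile.vi_attenuation
            f0 = f0 + rng.normal(0.0, profile.vi_jitter_sd)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
        wave = (amp * np.sin(2 * np.pi * f0 * t_event + phases[0])
                + amp * profile.harmonic_ratio
                * np.sin(2 * np.pi * 2 * f0 * t_event + phases[1]))
        sl = slice(i * samples_per_event, (i + 1) * samples_per_event)
        data[:, sl] += gains[:, None] * wave[None, :]

    return EEGRecording(channel_labels=channel_labels, fs=fs, data=data,
                        annotations=annotations, recording_id=recording_id)
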