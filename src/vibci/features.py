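"""Spectral features: Welch PSDs and the per-trial feature matrix.

Classifier features are the Welch PSD (2-s Hamming segments, 50%
overlap, density scaling) of each trial restricted to 3-36 Hz, computed
per electrode and concatenated electrode-major over the 10-channel
analysis montage.  Short screening epochs (1 s) instead use a single
zero-padded Hamming periodogram on a fine grid, which the peak-scoring
rule needs to resolve its ±0.05 Hz neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .recording import ANALYSIS_CHANNELS, Epoch

FEATURE_BAND = (3.0, 36.0)  # Hz, closed interval
WELCH_SEGMENT_S = 2.0
DEFAULT_HIGHRES_RESOLUTION = 0.025  # Hz


@dataclass(frozen=True)
class PSDVector:
    """Power spectral density on an explicit frequency grid.

    ``power`` may carry leading batch axes (e.g. trials x channels); the
    frequency axis is always the last one.
    """

    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # µV²/Hz, frequency on the last axis
    resolution: float  # Hz, grid spacing

    def __post_init__(self):
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "power", np.asarray(self.power, dtype=float))
        if self.power.shape[-1] != self.freqs.shape[-1]:
            raise ValueError("power's last axis must match the frequency grid")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    def band(self, lo: float, hi: float) -> "PSDVector":
        mask = (self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9)
        return PSDVector(self.freqs[mask], self.power[..., mask], self.resolution)


def welch_psd(x: np.ndarray, fs: float) -> PSDVector:
    """Welch estimate with 2-s Hamming segments and 50% overlap.

    Grid spacing is 1/2 Hz.  Signals shorter than one segment are
    rejected; short epochs belong to :func:`highres_psd`.
    """
    x = np.asarray(x, dtype=float)
    nperseg = round(WELCH_SEGMENT_S * fs)
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal of {x.shape[-1]} samples is shorter than one "
            f"{WELCH_SEGMENT_S:g}-s Welch segment at fs={fs}"
        )
    freqs, power = signal.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                                noverlap=nperseg // 2, detrend="constant",
                                scaling="density")
    return PSDVector(freqs, power, resolution=fs / nperseg)


def welch_segment_count(n_samples: int, fs: float) -> int:
    """Number of averaged segments for a signal of given length."""
    nperseg = round(WELCH_SEGMENT_S * fs)
    step = nperseg - nperseg // 2
    return max(0, (n_samples - nperseg) // step + 1)


def highres_psd(x: np.ndarray, fs: float,
                resolution: float = DEFAULT_HIGHRES_RESOLUTION) -> PSDVector:
    """Single Hamming-windowed, zero-padded periodogram on a fine grid.

    The grid spacing is fs/nfft with nfft chosen so the spacing does not
    exceed ``resolution``.  Zero padding interpolates the spectrum; it
    does not narrow the underlying window main lobe.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    x = np.asarray(x, dtype=float)
    nfft = int(np.ceil(fs / resolution))
    if nfft < x.shape[-1]:
        nfft = x.shape[-1]
    freqs, power = signal.periodogram(x, fs=fs, window="hamming", nfft=nfft,
                                      detrend="constant", scaling="density")
    return PSDVector(freqs, power, resolution=fs / nfft)


@dataclass
class FeatureMatrix:
    """Trials x (electrode-major PSD bins) with labels and provenance."""

    X: np.ndarray            # (n_trials, n_channels * n_bins)
    labels: list[str]        # class per trial
    recording_ids: list[str]
    freqs: np.ndarray        # the n_bins shared frequency grid (Hz)
    channels: tuple[str, ...]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        n_cols = len(self.channels) * len(self.freqs)
        if self.X.shape != (len(self.labels), n_cols):
            raise ValueError("feature matrix shape inconsistent with metadata")

    @property
    def column_names(self) -> list[str]:
        return [f"{ch}_{f:g}Hz" for ch in self.channels for f in self.freqs]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df.insert(0, "label", self.labels)
        df.insert(1, "recording_id", self.recording_ids)
        return df


def build_features(epochs: list[Epoch],
                   channels: tuple[str, ...] = ANALYSIS_CHANNELS) -> FeatureMatrix:
    """Welch-PSD feature rows for a list of same-shape epochs.

    Per trial and per analysis electrode the Welch PSD is restricted to
    the closed 3-36 Hz band and the per-electrode vectors concatenated in
    fixed electrode order.
    """
    if not epochs:
        raise ValueError("no epochs given")
    fs = epochs[0].fs
    n_samp = epochs[0].data.shape[1]
    for ep in epochs:
        if ep.fs != fs:
            raise ValueError("epochs mix sampling rates")
        if ep.data.shape[1] != n_samp:
            raise ValueError("epochs mix window lengths")
    ch_idx = [epochs[0].channel_labels.index(ch) for ch in channels]

    stack = np.stack([ep.data[ch_idx] for ep in epochs])  # (trials, ch, samp)
    banded = welch_psd(stack, fs).band(*FEATURE_BAND)
    X = banded.power.reshape(len(epochs), -1)
    return FeatureMatrix(X=X, labels=[ep.label for ep in epochs],
                         recording_ids=[ep.recording_id for ep in epochs],
                         freqs=banded.freqs, channels=tuple(channels))
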