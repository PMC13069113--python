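"""Offline filter chain and step-specific epoch extraction.

Three filters are applied in order: a 60 Hz low-pass (muscle and RF
noise), a 48-52 Hz notch (line noise) and a 3-36 Hz band-pass of overall
order 8 (Butterworth).  All three run forward-backward (zero phase) so
event onsets stay aligned between filtered and raw data.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .recording import EEGRecording, Epoch
from .simulate import ProtocolSpec

LOWPASS_HZ = 60.0
NOTCH_HZ = 50.0
NOTCH_BANDWIDTH_HZ = 4.0  # -3 dB edges at 48 and 52 Hz
BANDPASS_HZ = (3.0, 36.0)
MIN_FS = 120.0  # the 60 Hz low-pass edge needs headroom below Nyquist


def _design_chain(fs: float) -> list[np.ndarray]:
    """Second-order sections for the three filters, in application order."""
    low = signal.butter(4, LOWPASS_HZ, btype="low", fs=fs, output="sos")
    b, a = signal.iirnotch(NOTCH_HZ, NOTCH_HZ / NOTCH_BANDWIDTH_HZ, fs=fs)
    notch = signal.tf2sos(b, a)
    # butter() with N=4 and a band gives an order-8 band-pass transfer.
    band = signal.butter(4, BANDPASS_HZ, btype="bandpass", fs=fs, output="sos")
    return [low, notch, band]


def filter_chain(rec: EEGRecording) -> EEGRecording:
    """Apply low-pass, notch and band-pass to every channel, zero-phase.

    Returns a new recording with the same shape and annotations.
    """
    if rec.fs <= MIN_FS:
        raise ValueError(f"fs={rec.fs} Hz too low; the filter chain needs fs > {MIN_FS}")
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("recording contains non-finite samples")
    out = rec.data
    for sos in _design_chain(rec.fs):
        out = signal.sosfiltfilt(sos, out, axis=-1)
    return EEGRecording(channel_labels=rec.channel_labels, fs=rec.fs,
                        data=out, annotations=list(rec.annotations),
                        recording_id=rec.recording_id)


def chain_frequency_response(fs: float, freqs: np.ndarray) -> np.ndarray:
    """|H(f)| of the designed cascade; the oracle for attenuation tests."""
    h = np.ones_like(freqs, dtype=complex)
    for sos in _design_chain(fs):
        _, hi = signal.sosfreqz(sos, worN=freqs, fs=fs)
        h *= hi
    return np.abs(h)


def extract_epochs(rec: EEGRecording, protocol: ProtocolSpec) -> list[Epoch]:
    """Cut one epoch per annotation using the protocol's window.

    Windows are half-open [start, end) seconds from event onset; sample
    indices are floor(t * fs), so an epoch holds round((end-start)*fs)
    samples.
    """
    if not rec.annotations:
        raise ValueError("recording has no annotations to epoch")
    start, end = protocol.epoch_window
    n_per_epoch = round((end - start) * rec.fs)
    epochs: list[Epoch] = []
    for ann in rec.annotations:
        if end > ann.duration + 1e-9:
            raise ValueError(
                f"epoch window [{start}, {end}) exceeds the {ann.duration}s "
                f"event {ann.label!r} at {ann.onset:.3f}s"
            )
        first = int(np.floor((ann.onset + start) * rec.fs))
        sl = rec.data[:, first:first + n_per_epoch]
        if sl.shape[1] != n_per_epoch:
            raise ValueError(
                f"event {ann.label!r} at {ann.onset:.3f}s runs past the recording"
            )
        epochs.append(Epoch(label=ann.label, data=sl.copy(), window=(start, end),
                            fs=rec.fs, channel_labels=rec.channel_labels,
                            step_id=protocol.step_id,
                            recording_id=rec.recording_id))
    return epochs
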