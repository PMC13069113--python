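"""Persistence, run configuration and the end-to-end pipeline.

Recordings persist either as EDF+ (16-bit physical microvolts with TAL
event annotations; read back through MNE) or as a plain-text CSV
dialect (a samples x channels matrix plus an events sidecar and a JSON
metadata sidecar), selected by file extension.

``run_pipeline`` executes a full simulated session for one subject:
screening, frequency selection, ten offline imagery recordings,
temporal cross-validation, online-model selection and evaluation, and
the chance-level statistics, producing a deterministic JSON-able
report keyed by the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .classify import evaluate, select_online_model, temporal_cv
from .features import build_features
from .freq_select import score_candidates, select_couple
from .preprocess import extract_epochs, filter_chain
from .recording import REST_LABEL, Annotation, EEGRecording, imagery_label
from .simulate import DEFAULT_FS, ProtocolSpec, make_subject_profile, simulate_recording
from .stats_eval import chance_upper_bound

logger = logging.getLogger("vibci")


# ---------------------------------------------------------------------------
# EDF+ writing (16-bit) and reading through MNE

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _annotation_records(rec: EEGRecording, n_records: int) -> list[bytes]:
    """TAL byte blocks, one per 1-s data record."""
    by_record: list[list[bytes]] = [[] for _ in range(n_records)]
    for ann in rec.annotations:
        tal = (f"+{ann.onset:.6g}\x15{ann.duration:.6g}\x14"
               f"{ann.label}\x14\x00").encode("utf-8")
        by_record[min(int(ann.onset), n_records - 1)].append(tal)
    blocks = []
    for i, tals in enumerate(by_record):
        blocks.append(f"+{i}\x14\x14\x00".encode("ascii") + b"".join(tals))
    return blocks


def write_edf(path: str | Path, rec: EEGRecording) -> None:
    """Write an EDF+C file with one data record per second.

    Samples are quantized to 16 bits over each channel's physical
    range; annotations are stored as EDF+ TAL events.
    """
    rec.validate_annotations()
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise ValueError("EDF export requires a whole number of seconds")
    n_records = rec.n_samples // fs

    ann_blocks = _annotation_records(rec, n_records)
    ann_bytes = max(len(b) for b in ann_blocks)
    ann_samples = (ann_bytes + 1) // 2 + 1  # 2 bytes per sample, headroom

    phys_min, phys_max = [], []
    for ch in range(rec.n_channels):
        lo, hi = float(rec.data[ch].min()), float(rec.data[ch].max())
        if hi <= lo:
            lo, hi = lo - 1.0, lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)

    ns = rec.n_channels + 1
    header_bytes = 256 * (ns + 1)
    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X X X X", 80))
        fh.write(_edf_field("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(header_bytes), 8))
        fh.write(_edf_field("EDF+C", 44))
        fh.write(_edf_field(str(n_records), 8))
        fh.write(_edf_field("1", 8))
        fh.write(_edf_field(str(ns), 4))

        labels = list(rec.channel_labels) + ["EDF Annotations"]
        fh.write(b"".join(_edf_field(l, 16) for l in labels))
        fh.write(b"".join(_edf_field("", 80) for _ in labels))
        fh.write(b"".join(_edf_field("uV", 8) for _ in rec.channel_labels)
                 + _edf_field("", 8))
        fh.write(b"".join(_edf_field(f"{v:.6g}", 8) for v in phys_min)
                 + _edf_field("-1", 8))
        fh.write(b"".join(_edf_field(f"{v:.6g}", 8) for v in phys_max)
                 + _edf_field("1", 8))
        fh.write(b"".join(_edf_field(str(_EDF_DIG_MIN), 8) for _ in labels))
        fh.write(b"".join(_edf_field(str(_EDF_DIG_MAX), 8) for _ in labels))
        fh.write(b"".join(_edf_field("", 80) for _ in labels))
        fh.write(b"".join(_edf_field(str(fs), 8) for _ in rec.channel_labels)
                 + _edf_field(str(ann_samples), 8))
        fh.write(b"".join(_edf_field("", 32) for _ in labels))

        scale = [(phys_max[c] - phys_min[c]) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
                 for c in range(rec.n_channels)]
        for r in range(n_records):
            for c in range(rec.n_channels):
                chunk = rec.data[c, r * fs:(r + 1) * fs]
                dig = np.round((chunk - phys_min[c]) / scale[c]
                               + _EDF_DIG_MIN).astype("<i2")
                fh.write(dig.tobytes())
            block = ann_blocks[r].ljust(2 * ann_samples, b"\x00")
            fh.write(block)


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF/EDF+ recording (via MNE) back to microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE holds EEG in volts
    annotations = [Annotation(float(a["onset"]), float(a["duration"]),
                              str(a["description"]))
                   for a in raw.annotations]
    return EEGRecording(channel_labels=tuple(raw.ch_names),
                        fs=float(raw.info["sfreq"]), data=data,
                        annotations=annotations,
                        recording_id=Path(path).stem)


# ---------------------------------------------------------------------------
# CSV dialect: data matrix + events sidecar + JSON metadata sidecar

def _csv_sidecars(path: Path) -> tuple[Path, Path]:
    return (path.with_suffix(".events.csv"), path.with_suffix(".meta.json"))


def write_csv(path: str | Path, rec: EEGRecording) -> None:
    """Write the samples x channels matrix with events and metadata sidecars."""
    rec.validate_annotations()
    path = Path(path)
    pd.DataFrame(rec.data.T, columns=list(rec.channel_labels)).to_csv(
        path, index=False)
    events_path, meta_path = _csv_sidecars(path)
    pd.DataFrame(
        [(a.onset, a.duration, a.label) for a in rec.annotations],
        columns=["onset_s", "duration_s", "label"],
    ).to_csv(events_path, index=False)
    meta_path.write_text(json.dumps(
        {"fs": rec.fs, "channel_labels": list(rec.channel_labels),
         "recording_id": rec.recording_id}, indent=1) + "\n")


def read_csv(path: str | Path) -> EEGRecording:
    path = Path(path)
    events_path, meta_path = _csv_sidecars(path)
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed metadata sidecar {meta_path}: {exc}") from exc
    frame = pd.read_csv(path, float_precision="round_trip")
    if list(frame.columns) != list(meta["channel_labels"]):
        raise ValueError(f"{path}: data columns disagree with metadata channels")
    events = (pd.read_csv(events_path, float_precision="round_trip")
              if events_path.exists() else None)
    annotations = [] if events is None else [
        Annotation(float(r.onset_s), float(r.duration_s), str(r.label))
        for r in events.itertuples()
    ]
    return EEGRecording(channel_labels=tuple(meta["channel_labels"]),
                        fs=float(meta["fs"]), data=frame.to_numpy().T,
                        annotations=annotations,
                        recording_id=str(meta.get("recording_id", path.stem)))


def write_recording(path: str | Path, rec: EEGRecording) -> None:
    """Persist a recording; the format follows the file extension."""
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        write_edf(path, rec)
    elif suffix == ".csv":
        write_csv(path, rec)
    else:
        raise ValueError(f"unsupported recording format {suffix!r}")


def read_recording(path: str | Path) -> EEGRecording:
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return read_edf(path)
    if suffix == ".csv":
        return read_csv(path)
    raise ValueError(f"unsupported recording format {suffix!r}")


# ---------------------------------------------------------------------------
# Run configuration and the full pipeline

class RunConfig(BaseModel):
    """Everything a pipeline run depends on; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    fs: float = DEFAULT_FS
    profile: dict = Field(default_factory=dict)
    n_offline_recordings: int = 10
    score_resolution: float = 0.025
    chance_alpha: float = 0.01

    def config_hash(self) -> str:
        # canonical form: JSON-typed (string keys), sorted recursively
        payload = json.dumps(json.loads(self.model_dump_json()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Simulate and analyze one subject end to end.

    Stages: screening simulation -> filter chain -> epoching -> peak
    scoring and couple selection -> offline imagery simulation ->
    features -> temporal CV -> online-model selection -> online
    evaluation -> chance-level statistics.  The report is a plain dict,
    deterministic given the configuration.
    """
    seeds = [int(s) for s in
             np.random.SeedSequence(config.seed).generate_state(
                 3 + config.n_offline_recordings) >> np.uint32(1)]
    profile = make_subject_profile(seeds[0], config.profile)

    logger.info("step 1: screening simulation and frequency selection")
    step1 = ProtocolSpec.step_1()
    rec1 = simulate_recording(step1, profile, couple=None, seed=seeds[1],
                              fs=config.fs, recording_id="step1")
    epochs1 = extract_epochs(filter_chain(rec1), step1)
    score_table = score_candidates(epochs1, resolution=config.score_resolution)
    couple = select_couple(score_table)
    class_order = [imagery_label(couple.f_low), REST_LABEL,
                   imagery_label(couple.f_high)]

    logger.info("step 3: %d offline recordings at couple (%g, %g)",
                config.n_offline_recordings, couple.f_low, couple.f_high)
    step3 = ProtocolSpec.step_3(tuple(couple))
    offline_features = []
    for i in range(config.n_offline_recordings):
        rec = simulate_recording(step3, profile, couple=tuple(couple),
                                 seed=seeds[3 + i], fs=config.fs,
                                 recording_id=f"step3_{i:02d}")
        epochs = extract_epochs(filter_chain(rec), step3)
        offline_features.append(build_features(epochs))
    cv = temporal_cv(offline_features, class_order=class_order)

    logger.info("step 4: online session replay")
    step4 = ProtocolSpec.step_4(tuple(couple))
    rec4 = simulate_recording(step4, profile, couple=tuple(couple),
                              seed=seeds[2], fs=config.fs,
                              recording_id="step4")
    online_features = build_features(extract_epochs(filter_chain(rec4), step4))
    online_model = select_online_model(cv)
    online_acc, online_conf = evaluate(online_model, online_features)

    offline_bound = chance_upper_bound(
        step3.reps_per_class * config.n_offline_recordings, 3,
        config.chance_alpha)
    online_bound = chance_upper_bound(step4.reps_per_class, 3,
                                      config.chance_alpha)

    report = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "profile_gains_uv": {f"{f:g}": g
                             for f, g in sorted(profile.response_gain.items())},
        "score_table": {f"{f:g}": s for f, s in sorted(score_table.items())},
        "selected_couple_hz": [couple.f_low, couple.f_high],
        "offline": {
            "fold_accuracies_pct": cv.fold_accuracies,
            "mean_accuracy_pct": cv.mean_accuracy,
            "std_accuracy_pct": cv.std_accuracy,
            "best_fold": cv.best_fold,
            "chance_upper_bound_pct": offline_bound.bound,
        },
        "online": {
            "accuracy_pct": online_acc,
            "confusion": {"classes": class_order,
                          "matrix": online_conf.to_numpy().tolist()},
            "chance_upper_bound_pct": online_bound.bound,
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n")
        pd.DataFrame({"fold": range(len(cv.fold_accuracies)),
                      "accuracy_pct": cv.fold_accuracies}).to_csv(
            outdir / "cv_folds.csv", index=False)
        online_conf.to_csv(outdir / "confusion_online.csv")
    return report
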