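"""Reading and writing PCG audio, onset sidecars, configs and reports.

WAV files are mono RIFF, PCM-16 by default (float-32 optional).  Onset
labels travel in a delimited-text sidecar with columns
``recording_id, component, onset_seconds, class_label`` -- one row per
S1/S2 onset.  Pipeline configuration is a flat YAML document; unknown keys
are rejected with the list of valid keys.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .recording import CLASSES, PcgRecording

SIDECAR_COLUMNS = ["recording_id", "component", "onset_seconds", "class_label"]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    The working rate of 600 Hz satisfies Nyquist for the S2 band (20-250 Hz)
    and the default 1.6 s frame spans roughly two cardiac cycles
    (960 samples at 600 Hz); 0.8 s is the supported single-cycle alternative.
    """

    target_rate_hz: float = 600.0
    frame_length_s: float = 1.6
    model_name: str = "gru"
    cv_folds: int = 10
    validation_fraction_of_train: float = 0.2
    seed: int = 0
    # training hyperparameters (defaults follow the GRU screening recipe)
    n_layers: int = 2
    units: int = 64
    learning_rate: float = 0.001
    l2_lambda: float = 0.0001
    batch_size: int = 64
    epochs: int = 50
    chunk_size: int = 1
    # segmentation / framing
    feature_rate_hz: float = 50.0
    use_true_onsets: bool = False
    stratified: bool = True
    grouping: str = "frame"
    # synthesis scale (used by the end-to-end runner)
    recordings_per_class: int = 10
    n_cycles: int = 20
    snr_db: float = 25.0

    def __post_init__(self):
        if self.target_rate_hz <= 2 * 250.0:
            raise ValueError("target_rate_hz must exceed 500 Hz (Nyquist for the S2 band)")
        if self.frame_length_s <= 0:
            raise ValueError("frame_length_s must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.validation_fraction_of_train < 1:
            raise ValueError("validation_fraction_of_train must be in (0, 1)")
        if self.model_name not in {"gru", "lstm", "fcn", "svm"}:
            raise ValueError("model_name must be one of gru/lstm/fcn/svm")
        if self.grouping not in {"frame", "recording"}:
            raise ValueError("grouping must be 'frame' or 'recording'")

    @property
    def frame_samples(self) -> int:
        return int(round(self.frame_length_s * self.target_rate_hz))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected naming the valid ones."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ValueError(
            f"unknown config keys {unknown}; valid keys are {sorted(valid)}"
        )
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, default_flow_style=False, sort_keys=True)


def write_recording(recording: PcgRecording, path: str | Path,
                    fmt: str = "pcm16", sidecar: str | Path | None = None) -> None:
    """Write a mono WAV (plus an optional onset sidecar)."""
    x = np.clip(recording.samples, -1.0, 1.0)
    rate = int(round(recording.sampling_rate_hz))
    if fmt == "pcm16":
        wavfile.write(path, rate, (x * 32767.0).round().astype(np.int16))
    elif fmt == "float32":
        wavfile.write(path, rate, x.astype(np.float32))
    else:
        raise ValueError("fmt must be 'pcm16' or 'float32'")
    if sidecar is not None:
        write_sidecar([recording], sidecar)


def write_sidecar(recordings: list[PcgRecording], path: str | Path) -> None:
    rows = []
    for rec in recordings:
        for comp, onsets in (("S1", rec.true_s1_onsets_s), ("S2", rec.true_s2_onsets_s)):
            for t in onsets:
                rows.append((rec.recording_id, comp, float(t), rec.class_label or ""))
    df = pd.DataFrame(rows, columns=SIDECAR_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_sidecar(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SIDECAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sidecar missing columns {missing}")
    for (rid, comp), grp in df.groupby(["recording_id", "component"], sort=False):
        vals = grp["onset_seconds"].to_numpy()
        bad = np.flatnonzero(np.diff(vals) <= 0)
        if bad.size:
            row = grp.index[bad[0] + 1]
            raise ValueError(
                f"sidecar onsets not strictly increasing for {rid}/{comp} at row {row}"
            )
    return df


def read_recording(path: str | Path, sidecar: str | Path | None = None,
                   multichannel: str = "reject") -> PcgRecording:
    """Read a WAV file (and attach sidecar onsets when present).

    PCM-16 samples are scaled to [-1, 1).  Multi-channel input is rejected
    by default; pass ``multichannel="mean"`` to average channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        if multichannel == "mean":
            data = data.mean(axis=1)
        else:
            raise ValueError(f"{path.name}: expected mono WAV, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0  # inverse of the write scale
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    else:
        samples = data.astype(np.float64)
    rec_id = path.stem
    s1, s2, label = np.empty(0), np.empty(0), None
    if sidecar is not None and Path(sidecar).exists():
        df = read_sidecar(sidecar)
        sub = df[df["recording_id"] == rec_id]
        if len(df) and sub.empty:
            raise ValueError(
                f"sidecar {Path(sidecar).name} has no rows for recording id {rec_id!r}"
            )
        s1 = sub.loc[sub["component"] == "S1", "onset_seconds"].to_numpy()
        s2 = sub.loc[sub["component"] == "S2", "onset_seconds"].to_numpy()
        labels = sub["class_label"].dropna().unique()
        label = str(labels[0]) if labels.size and str(labels[0]) in CLASSES else None
    return PcgRecording(samples=samples, sampling_rate_hz=float(rate),
                        class_label=label, true_s1_onsets_s=s1,
                        true_s2_onsets_s=s2, recording_id=rec_id)


def save_report(report, out_dir: str | Path) -> None:
    """Serialize a cross-validation report: fold table, confusion matrix, JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"fold": np.arange(1, len(report.fold_accuracies) + 1),
                  "accuracy": report.fold_accuracies}).to_csv(
        out / "fold_accuracies.csv", index=False, float_format="%.6f")
    cm = pd.DataFrame(report.confusion, index=list(report.classes),
                      columns=list(report.classes))
    cm.index.name = "true"
    cm.to_csv(out / "confusion_matrix.csv")
    summary = {
        "model": report.model_name,
        "mean_accuracy": report.mean_accuracy,
        "sd_accuracy": report.sd_accuracy,
        "pooled_accuracy": report.pooled_accuracy,
        "precision": {c: report.precision[i] for i, c in enumerate(report.classes)},
        "recall": {c: report.recall[i] for i, c in enumerate(report.classes)},
        "manifest": report.manifest,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
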