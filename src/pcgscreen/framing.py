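"""Period-synchronous framing: fixed-length windows anchored at S1 onsets.

Each S1 onset opens one candidate frame of exactly
``round(frame_length_s * rate)`` samples; candidates running past the end
of the recording are dropped.  With the default 1.6 s frame and ~0.6-0.8 s
cycles, consecutive frames overlap by ``frame_length - cycle_length``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import PipelineConfig
from .preprocess import Frame, normalize_frame, resample
from .recording import CLASS_CODES, PcgRecording
from .segmentation import EmissionModel, mark_s1_onsets

logger = logging.getLogger(__name__)


@dataclass
class FrameDataset:
    """Fixed-length normalized frames with labels and provenance."""

    frames: list[Frame]
    frame_length_s: float
    target_rate_hz: float

    def __post_init__(self):
        n = self.frame_samples
        for f in self.frames:
            if f.values.size != n:
                raise ValueError(
                    f"frame from {f.recording_id} has {f.values.size} samples, "
                    f"expected {n}")

    @property
    def frame_samples(self) -> int:
        return int(round(self.frame_length_s * self.target_rate_hz))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.frames:
            counts[f.class_label] = counts.get(f.class_label, 0) + 1
        return counts

    def X(self) -> np.ndarray:
        return np.stack([f.values for f in self.frames])

    def y(self) -> np.ndarray:
        return np.array([CLASS_CODES[f.class_label] for f in self.frames])

    def groups(self) -> np.ndarray:
        return np.array([f.recording_id for f in self.frames])


def segment_frames(recording: PcgRecording, s1_onsets_s: np.ndarray,
                   frame_length_s: float) -> list[Frame]:
    """Cut one frame per S1 onset; incomplete tail frames are dropped."""
    onsets = np.asarray(s1_onsets_s, dtype=float)
    if onsets.size == 0:
        logger.info("no S1 onsets for %s; emitting no frames", recording.recording_id)
        return []
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("S1 onsets must be strictly increasing")
    rate = recording.sampling_rate_hz
    L = int(round(frame_length_s * rate))
    n = recording.samples.size
    frames = []
    for onset in onsets:
        start = int(np.floor(onset * rate))
        if start < 0 or start + L > n:
            continue
        frames.append(Frame(values=recording.samples[start:start + L].copy(),
                            class_label=recording.class_label,
                            recording_id=recording.recording_id,
                            anchor_onset_s=float(onset)))
    return frames


def build_dataset(recordings: list[PcgRecording], config: PipelineConfig,
                  emissions: EmissionModel | None = None) -> FrameDataset:
    """Resample, locate onsets (detected or ground-truth), frame and normalize.

    When ``config.use_true_onsets`` is false an emission model is required
    and onsets come from the HSMM segmenter.
    """
    if not recordings:
        raise ValueError("no recordings supplied")
    if not config.use_true_onsets and emissions is None:
        raise ValueError("detected-onset mode requires a fitted emission model")
    frames: list[Frame] = []
    for rec in recordings:
        work = resample(rec, config.target_rate_hz)
        if config.use_true_onsets:
            onsets = work.true_s1_onsets_s
        else:
            onsets = mark_s1_onsets(work, emissions, config.feature_rate_hz).s1_onsets_s
        cut = segment_frames(work, onsets, config.frame_length_s)
        if not cut:
            logger.warning("recording %s produced no frames (duration %.2f s, "
                           "%d onsets)", rec.recording_id, work.duration_s, onsets.size)
        frames.extend(normalize_frame(f) for f in cut)
    return FrameDataset(frames, config.frame_length_s, config.target_rate_hz)
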