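"""Resampling to the working rate and per-frame min-max normalization.

Recordings are brought to 600 Hz (anti-aliased polyphase resampling) and
each fixed-length frame is mapped to [0, 1] by

    X = (x - x_min) / (x_max - x_min)

with frame-local extrema.  Constant frames would divide by zero; they are
mapped to all-zeros and flagged as degenerate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .recording import PcgRecording

logger = logging.getLogger(__name__)


@dataclass
class Frame:
    """One fixed-length window of a recording, anchored at an S1 onset."""

    values: np.ndarray
    class_label: str | None
    recording_id: str
    anchor_onset_s: float
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("frame values must be one-dimensional")


def resample(recording: PcgRecording, target_rate_hz: float) -> PcgRecording:
    """Rate-convert a recording with a Kaiser-windowed polyphase filter.

    Onset times are in seconds and therefore unchanged; the state path, when
    present, is carried over by nearest-index mapping.
    """
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    if recording.samples.size == 0:
        raise ValueError("cannot resample an empty recording")
    if target_rate_hz <= 2 * 250.0:
        warnings.warn(
            f"target rate {target_rate_hz} Hz is at or below Nyquist for the "
            "S2 band (20-250 Hz); aliasing is likely", stacklevel=2)
    src = recording.sampling_rate_hz
    if np.isclose(src, target_rate_hz):
        return recording
    frac = Fraction(target_rate_hz / src).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = resample_poly(recording.samples, up, down, window=("kaiser", 5.0))

    path = None
    if recording.true_state_path is not None:
        idx = np.minimum(
            (np.arange(out.size) * src / target_rate_hz).round().astype(int),
            recording.true_state_path.size - 1)
        path = recording.true_state_path[idx]
    return PcgRecording(
        samples=out, sampling_rate_hz=target_rate_hz,
        class_label=recording.class_label,
        true_s1_onsets_s=recording.true_s1_onsets_s.copy(),
        true_s2_onsets_s=recording.true_s2_onsets_s.copy(),
        true_state_path=path, recording_id=recording.recording_id)


def normalize_frame(frame: Frame) -> Frame:
    """Min-max normalize one frame to [0, 1].

    Idempotent on its own output and invariant under positive affine
    rescaling of the input.  A constant frame maps to all zeros.
    """
    if frame.values.size == 0:
        raise ValueError("cannot normalize an empty frame")
    x = frame.values
    x_min, x_max = x.min(), x.max()
    if x_max == x_min:
        logger.warning("degenerate constant frame (%s @ %.3f s) mapped to zeros",
                       frame.recording_id, frame.anchor_onset_s)
        values = np.zeros_like(x)
    else:
        values = (x - x_min) / (x_max - x_min)
    return replace(frame, values=values, normalized=True)
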