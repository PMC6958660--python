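"""Core in-memory representation of a phonocardiogram recording.

A cardiac cycle passes through four acoustic states in fixed order:
S1 (first heart sound, start of systole), systole, S2 (second heart
sound, start of diastole) and diastole.  State paths are stored as one
integer code per sample using the ordering in ``STATES``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STATES: tuple[str, ...] = ("S1", "systole", "S2", "diastole")
STATE_CODES = {name: i for i, name in enumerate(STATES)}
N_STATES = len(STATES)

CLASSES: tuple[str, ...] = ("normal", "HFpEF", "HFrEF")
CLASS_CODES = {name: i for i, name in enumerate(CLASSES)}


def next_state(code: int) -> int:
    """Successor in the deterministic cycle S1 -> systole -> S2 -> diastole -> S1."""
    return (code + 1) % N_STATES


@dataclass
class PcgRecording:
    """A mono PCG waveform with optional ground-truth annotations."""

    samples: np.ndarray
    sampling_rate_hz: float
    class_label: str | None = None
    true_s1_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_s2_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_state_path: np.ndarray | None = None
    recording_id: str = "rec"
    components: dict[str, np.ndarray] | None = None  # clean parts, for synthesis bookkeeping

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.true_s1_onsets_s = np.asarray(self.true_s1_onsets_s, dtype=np.float64)
        self.true_s2_onsets_s = np.asarray(self.true_s2_onsets_s, dtype=np.float64)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        dur = self.duration_s
        for name, onsets in (("S1", self.true_s1_onsets_s), ("S2", self.true_s2_onsets_s)):
            if onsets.size:
                if np.any(np.diff(onsets) <= 0):
                    raise ValueError(f"{name} onsets must be strictly increasing")
                if onsets[0] < 0 or onsets[-1] >= dur:
                    raise ValueError(f"{name} onsets must lie within [0, duration)")
        if self.true_state_path is not None:
            self.true_state_path = np.asarray(self.true_state_path, dtype=np.int64)
            if self.true_state_path.shape != self.samples.shape:
                raise ValueError("state path must have exactly one label per sample")
            _validate_cyclic(self.true_state_path)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    def onsets_from_state_path(self) -> tuple[np.ndarray, np.ndarray]:
        """Decode S1/S2 onset times from the stored per-sample state path."""
        if self.true_state_path is None:
            raise ValueError("recording carries no state path")
        return decode_onsets(self.true_state_path, self.sampling_rate_hz)


def decode_onsets(path: np.ndarray, rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (S1 onsets, S2 onsets) in seconds from run starts of a state path."""
    path = np.asarray(path)
    starts = np.flatnonzero(np.diff(path) != 0) + 1
    starts = np.concatenate(([0], starts))
    s1 = starts[path[starts] == STATE_CODES["S1"]] / rate_hz
    s2 = starts[path[starts] == STATE_CODES["S2"]] / rate_hz
    return s1, s2


def _validate_cyclic(path: np.ndarray) -> None:
    change = np.flatnonzero(np.diff(path) != 0)
    bad = [(int(i), int(path[i]), int(path[i + 1]))
           for i in change if path[i + 1] != next_state(path[i])]
    if bad:
        i, a, b = bad[0]
        raise ValueError(
            f"state path violates cyclic order at sample {i}: "
            f"{STATES[a]} -> {STATES[b]}"
        )
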