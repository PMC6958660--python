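"""Synthetic phonocardiogram generator with known S1/S2 onsets.

Each cardiac cycle is built from two Gaussian-amplitude-windowed sinusoid
chirps: S1 (band 10-200 Hz) at the start of the cycle and S2 (band
20-250 Hz) at the systole/diastole boundary.  The three screening classes
(normal, HFpEF, HFrEF) are emulated as acoustic surrogates -- per-class
multipliers on component amplitude and bandwidth, optional low-frequency
content and a soft systolic murmur -- not as clinical claims.  White
Gaussian noise is added at a configurable SNR.

Every waveform carries its ground-truth onset lists and per-sample state
path, so the downstream segmenter and classifiers can be trained and
scored without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .recording import CLASSES, STATE_CODES, PcgRecording


@dataclass(frozen=True)
class ClassProfile:
    """Acoustic surrogate for one screening class.

    Multipliers apply to the base S1/S2 chirps; ``lf_amp`` adds a
    low-frequency (3-15 Hz) baseline component and ``murmur_amp`` a soft
    band-limited noise burst inside systole.
    """

    s1_amp: float = 1.0
    s2_amp: float = 0.8
    s1_band_scale: float = 1.0
    s2_band_scale: float = 1.0
    lf_amp: float = 0.0
    murmur_amp: float = 0.0


#: Default class surrogates.  HFrEF halves the S1 amplitude (weakened
#: ventricular contraction surrogate) and adds low-frequency content plus a
#: murmur; HFpEF shifts spectral content downward and boosts S2.
DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "normal": ClassProfile(),
    "HFpEF": ClassProfile(s1_amp=0.9, s2_amp=1.15, s1_band_scale=0.75,
                          s2_band_scale=0.85, lf_amp=0.25, murmur_amp=0.12),
    "HFrEF": ClassProfile(s1_amp=0.5, s2_amp=1.0, s1_band_scale=0.9,
                          lf_amp=0.4, murmur_amp=0.25),
}


@dataclass
class SynthConfig:
    """Generation parameters; defaults reflect physiologically plausible values."""

    sampling_rate_hz: float = 2000.0
    n_cycles: int = 20
    cycle_duration_interval_s: tuple[float, float] = (0.6, 0.8)
    s1_band_hz: tuple[float, float] = (10.0, 200.0)
    s2_band_hz: tuple[float, float] = (20.0, 250.0)
    s1_duration_s: float = 0.12
    s2_duration_s: float = 0.10
    systole_fraction: float = 0.42
    class_label: str = "normal"
    class_profile: ClassProfile = field(default_factory=ClassProfile)
    snr_db: float = 25.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be non-negative")
        lo, hi = self.cycle_duration_interval_s
        if not (0.5 <= lo <= hi <= 1.0):
            raise ValueError("cycle duration interval must lie within [0.5, 1.0] s")
        if self.s1_duration_s <= 0 or self.s2_duration_s <= 0:
            raise ValueError("component durations must be positive")
        if not 0 < self.systole_fraction < 1:
            raise ValueError("systole_fraction must be in (0, 1)")
        if self.class_label not in CLASSES:
            raise ValueError(f"class_label must be one of {CLASSES}")
        if lo <= self.s1_duration_s + self.s2_duration_s:
            raise ValueError("cycle duration must exceed s1_duration + s2_duration")


class CycleSegment(NamedTuple):
    waveform: np.ndarray
    onsets: dict[str, float]          # "s1_onset", "s2_onset" in seconds
    state_labels: np.ndarray          # int code per sample
    components: dict[str, np.ndarray]  # clean additive parts


def _chirp_burst(n: int, fs: float, duration_s: float, band: tuple[float, float],
                 band_scale: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-windowed downward chirp confined well inside `band`."""
    lo, hi = band
    width = (hi - lo) * band_scale
    f_hi = lo + 0.62 * width * (1.0 + 0.05 * rng.standard_normal())
    f_lo = lo + 0.22 * width * (1.0 + 0.05 * rng.standard_normal())
    f_hi = min(max(f_hi, lo + 0.05 * width), hi)
    f_lo = min(max(f_lo, lo + 0.02 * width), f_hi)
    t = np.arange(n) / fs
    # instantaneous frequency sweeps f_hi -> f_lo over the burst
    phase = 2 * np.pi * (f_hi * t - (f_hi - f_lo) * t**2 / (2 * duration_s))
    window = np.exp(-0.5 * ((t - duration_s / 2) / (duration_s / 7)) ** 2)
    return amp * window * np.sin(phase + rng.uniform(0, 2 * np.pi))


def generate_cycle(config: SynthConfig, cycle_duration_s: float,
                   rng: np.random.Generator) -> CycleSegment:
    """Synthesize one noiseless cardiac cycle.

    S1 starts at time 0, S2 at ``systole_fraction * cycle_duration_s``; the
    gaps are silent apart from class-profile murmur/low-frequency content.
    State labels follow the component support intervals.
    """
    if cycle_duration_s <= 0:
        raise ValueError("cycle_duration_s must be positive")
    if cycle_duration_s <= config.s1_duration_s + config.s2_duration_s:
        raise ValueError("cycle too short for the configured S1/S2 durations")
    fs = config.sampling_rate_hz
    n = int(round(cycle_duration_s * fs))
    prof = config.class_profile

    s2_onset_s = config.systole_fraction * cycle_duration_s
    if s2_onset_s <= config.s1_duration_s or s2_onset_s + config.s2_duration_s >= cycle_duration_s:
        raise ValueError("systole_fraction incompatible with component durations")

    n_s1 = int(round(config.s1_duration_s * fs))
    n_s2 = int(round(config.s2_duration_s * fs))
    i_s2 = int(round(s2_onset_s * fs))

    s1 = np.zeros(n)
    s1[:n_s1] = _chirp_burst(n_s1, fs, config.s1_duration_s, config.s1_band_hz,
                             prof.s1_band_scale, prof.s1_amp, rng)
    s2 = np.zeros(n)
    s2[i_s2:i_s2 + n_s2] = _chirp_burst(n_s2, fs, config.s2_duration_s,
                                        config.s2_band_hz, prof.s2_band_scale,
                                        prof.s2_amp, rng)

    murmur = np.zeros(n)
    if prof.murmur_amp > 0:
        lo_i, hi_i = n_s1, i_s2
        m = hi_i - lo_i
        if m > 4:
            noise = rng.standard_normal(m)
            # soft band-limited murmur: smooth the white noise then taper
            kernel = np.hanning(max(3, int(fs / 150)))
            noise = np.convolve(noise, kernel / kernel.sum(), mode="same")
            murmur[lo_i:hi_i] = prof.murmur_amp * np.hanning(m) * noise / (np.std(noise) + 1e-12)

    lf = np.zeros(n)
    if prof.lf_amp > 0:
        f = rng.uniform(3.0, 15.0)
        t = np.arange(n) / fs
        lf = prof.lf_amp * 0.3 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))

    states = np.full(n, STATE_CODES["diastole"], dtype=np.int64)
    states[:n_s1] = STATE_CODES["S1"]
    states[n_s1:i_s2] = STATE_CODES["systole"]
    states[i_s2:i_s2 + n_s2] = STATE_CODES["S2"]

    waveform = s1 + s2 + murmur + lf
    return CycleSegment(waveform, {"s1_onset": 0.0, "s2_onset": s2_onset_s},
                        states, {"s1": s1, "s2": s2, "murmur": murmur, "lf": lf})


def generate_recording(config: SynthConfig) -> PcgRecording:
    """Concatenate jittered cycles and add white noise at ``snr_db``."""
    if config.n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(config.rng_seed)
    lo, hi = config.cycle_duration_interval_s

    parts, paths = [], []
    comps: dict[str, list[np.ndarray]] = {k: [] for k in ("s1", "s2", "murmur", "lf")}
    s1_onsets, s2_onsets = [], []
    t0 = 0.0
    fs = config.sampling_rate_hz
    n_total = 0
    for _ in range(config.n_cycles):
        dur = rng.uniform(lo, hi)
        cyc = generate_cycle(config, dur, rng)
        t0 = n_total / fs
        s1_onsets.append(t0 + cyc.onsets["s1_onset"])
        s2_onsets.append(t0 + cyc.onsets["s2_onset"])
        parts.append(cyc.waveform)
        paths.append(cyc.state_labels)
        for k in comps:
            comps[k].append(cyc.components[k])
        n_total += cyc.waveform.size

    clean = np.concatenate(parts)
    path = np.concatenate(paths)
    power = float(np.mean(clean**2))
    sigma = np.sqrt(power / 10 ** (config.snr_db / 10)) if power > 0 else 0.0
    noise = sigma * rng.standard_normal(clean.size)

    components = {k: np.concatenate(v) for k, v in comps.items()}
    components["clean"] = clean
    components["noise"] = noise
    return PcgRecording(
        samples=clean + noise,
        sampling_rate_hz=fs,
        class_label=config.class_label,
        true_s1_onsets_s=np.asarray(s1_onsets),
        true_s2_onsets_s=np.asarray(s2_onsets),
        true_state_path=path,
        recording_id=f"{config.class_label}-seed{config.rng_seed}",
        components=components,
    )


def generate_dataset(per_class_counts: dict[str, int], base_config: SynthConfig,
                     profiles: dict[str, ClassProfile] | None = None) -> list[PcgRecording]:
    """Generate a labelled multi-class dataset in randomized order.

    Per-recording seeds are derived from ``base_config.rng_seed`` via a seed
    sequence, so the same base seed reproduces the identical dataset.
    """
    profiles = profiles if profiles is not None else DEFAULT_PROFILES
    for label, count in per_class_counts.items():
        if label not in CLASSES:
            raise ValueError(f"unknown class label {label!r}")
        if count < 0:
            raise ValueError("counts must be >= 0")
    ss = np.random.SeedSequence(base_config.rng_seed)
    total = sum(per_class_counts.values())
    children = ss.spawn(total + 1)
    shuffle_rng = np.random.default_rng(children[0])

    recordings: list[PcgRecording] = []
    i = 1
    for label in CLASSES:
        for k in range(per_class_counts.get(label, 0)):
            seed = int(children[i].generate_state(1)[0] % (2**31))
            cfg = replace(base_config, class_label=label,
                          class_profile=profiles[label], rng_seed=seed)
            rec = generate_recording(cfg)
            rec.recording_id = f"{label}-{k:03d}"
            recordings.append(rec)
            i += 1
    shuffle_rng.shuffle(recordings)
    return recordings
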