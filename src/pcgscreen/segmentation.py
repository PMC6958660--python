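"""S1-onset localization with a duration-dependent hidden semi-Markov model.

The segmenter follows the logistic-regression HSMM recipe that is standard
for heart-sound segmentation: envelope features are computed at a reduced
feature rate (50 Hz), per-state logistic regressions provide emission
posteriors, state durations carry truncated-Gaussian priors tied to the
estimated cardiac cycle length, and a duration-dependent Viterbi pass
returns the maximum a-posteriori state path over the fixed cycle
S1 -> systole -> S2 -> diastole.  S1 onsets are the starts of decoded S1
runs.

Edge semantics: the decode may enter and leave mid-cycle, so the first and
last runs are scored with the duration survival probability P(D >= d)
instead of the exact duration probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import butter, filtfilt, hilbert, resample_poly
from sklearn.linear_model import LogisticRegression

from .recording import N_STATES, STATES, PcgRecording

FEATURE_NAMES = ("homomorphic", "hilbert", "band_power")

_LOG_QUARTER = float(np.log(1.0 / N_STATES))
_NEG_INF = -np.inf


@dataclass
class EnvelopeFeatures:
    """Per-tick feature matrix (ticks x channels), channels scaled to [0, 1]."""

    matrix: np.ndarray
    feature_rate_hz: float
    names: tuple[str, ...] = FEATURE_NAMES

    @property
    def n_ticks(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SegmentationResult:
    state_path: np.ndarray          # int state code per feature tick
    s1_onsets_s: np.ndarray
    log_score: float
    feature_rate_hz: float


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    # near-constant channels (silent input) would amplify float noise
    if hi - lo <= 1e-9 * max(1.0, abs(hi)):
        return np.zeros_like(col)
    return (col - lo) / (hi - lo)


def extract_envelope_features(recording: PcgRecording,
                              feature_rate_hz: float = 50.0) -> EnvelopeFeatures:
    """Homomorphic, Hilbert and band-power envelopes at the feature rate."""
    fs = recording.sampling_rate_hz
    x = recording.samples
    if x.size < fs / feature_rate_hz:
        raise ValueError("recording shorter than one feature window")
    analytic = np.abs(hilbert(x))
    # homomorphic envelope: low-pass the log magnitude, exponentiate back
    b, a = butter(2, min(8.0 / (fs / 2), 0.99), btype="low")
    homo = np.exp(filtfilt(b, a, np.log(analytic + 1e-10)))
    hilb = filtfilt(b, a, analytic)
    # coarse band power in the heart-sound band
    lo, hi = 25.0 / (fs / 2), min(140.0 / (fs / 2), 0.99)
    bb, ab = butter(2, [lo, hi], btype="band")
    band = filtfilt(b, a, np.abs(hilbert(filtfilt(bb, ab, x))))

    frac = Fraction(feature_rate_hz / fs).limit_denominator(10_000)
    cols = []
    for env in (homo, hilb, band):
        ds = resample_poly(env, frac.numerator, frac.denominator)
        cols.append(_minmax(np.maximum(ds, 0.0)))
    return EnvelopeFeatures(np.column_stack(cols), feature_rate_hz)


def state_path_at_feature_rate(recording: PcgRecording, feature_rate_hz: float,
                               n_ticks: int) -> np.ndarray:
    """Nearest-index projection of the per-sample state path to feature ticks."""
    if recording.true_state_path is None:
        raise ValueError("recording carries no ground-truth state path")
    fs = recording.sampling_rate_hz
    idx = np.minimum((np.arange(n_ticks) * fs / feature_rate_hz).round().astype(int),
                     recording.true_state_path.size - 1)
    return recording.true_state_path[idx]


class EmissionModel:
    """One-vs-rest logistic regressions mapping features to state posteriors."""

    def __init__(self, models: list[LogisticRegression]):
        self.models = models

    def log_posteriors(self, features: EnvelopeFeatures) -> np.ndarray:
        """(ticks x states) log posterior matrix; rows normalized."""
        X = features.matrix
        probs = np.column_stack([m.predict_proba(X)[:, 1] for m in self.models])
        probs = np.clip(probs, 1e-12, None)
        probs /= probs.sum(axis=1, keepdims=True)
        return np.log(probs)


def fit_emissions(features_list: list[EnvelopeFeatures],
                  state_paths: list[np.ndarray]) -> EmissionModel:
    """Fit per-state logistic regressions on tick-labelled envelope features."""
    X = np.vstack([f.matrix for f in features_list])
    y = np.concatenate(state_paths)
    if X.shape[0] != y.size:
        raise ValueError("features and state paths are not aligned")
    present = set(np.unique(y).tolist())
    missing = [STATES[s] for s in range(N_STATES) if s not in present]
    if missing:
        raise ValueError(f"training labels contain no ticks for state(s) {missing}")
    models = []
    for s in range(N_STATES):
        lr = LogisticRegression(C=100.0, max_iter=1000)
        lr.fit(X, (y == s).astype(int))
        models.append(lr)
    return EmissionModel(models)


def estimate_heart_rate(features: EnvelopeFeatures,
                        lag_window_s: tuple[float, float] = (0.5, 1.0),
                        default_systole_fraction: float = 0.42,
                        ) -> tuple[float, float]:
    """Cycle length from the autocorrelation peak of the homomorphic envelope.

    The systole fraction is not reliably estimable from the envelope alone
    and is returned as a fixed physiological prior.
    """
    fr = features.feature_rate_hz
    x = features.matrix[:, 0] - features.matrix[:, 0].mean()
    lag_lo = int(round(lag_window_s[0] * fr))
    lag_hi = int(round(lag_window_s[1] * fr))
    if x.size <= lag_hi or np.allclose(x, 0):
        raise ValueError(
            "no admissible autocorrelation peak; provide a longer recording "
            "(need at least two cardiac cycles)")
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    window = ac[lag_lo:lag_hi + 1]
    peak = int(np.argmax(window)) + lag_lo
    if ac[peak] <= 0:
        raise ValueError(
            "no admissible autocorrelation peak; provide a longer recording "
            "(need at least two cardiac cycles)")
    return peak / fr, default_systole_fraction


@dataclass
class HsmmModel:
    """Emission model plus per-state truncated-Gaussian duration priors (ticks)."""

    emissions: EmissionModel
    dur_mean: np.ndarray
    dur_sd: np.ndarray
    dur_min: np.ndarray
    dur_max: np.ndarray
    feature_rate_hz: float

    def __post_init__(self):
        for arr in (self.dur_mean, self.dur_sd, self.dur_min, self.dur_max):
            if np.asarray(arr).shape != (N_STATES,):
                raise ValueError("duration arrays must have one entry per state")
        if np.any(self.dur_min < 1) or np.any(self.dur_max < self.dur_min):
            raise ValueError("duration supports must be positive and bounded")

    def duration_log_pmf(self) -> list[np.ndarray]:
        """Per state: log pmf over durations 1..dur_max (entries < dur_min are -inf)."""
        out = []
        for s in range(N_STATES):
            d = np.arange(1, int(self.dur_max[s]) + 1, dtype=float)
            logw = -0.5 * ((d - self.dur_mean[s]) / self.dur_sd[s]) ** 2
            logw[d < self.dur_min[s]] = _NEG_INF
            mx = logw.max()
            pmf = logw - (mx + np.log(np.exp(logw - mx).sum()))
            out.append(pmf)
        return out

    def duration_log_survivor(self) -> list[np.ndarray]:
        """Per state: log P(D >= d) for d = 1..dur_max."""
        out = []
        for pmf in self.duration_log_pmf():
            p = np.exp(pmf)
            surv = np.cumsum(p[::-1])[::-1]
            out.append(np.log(np.clip(surv, 1e-300, None)))
        return out


def adapt_durations(emissions: EmissionModel, cycle_s: float,
                    systole_fraction: float, feature_rate_hz: float,
                    s1_duration_s: float = 0.12, s2_duration_s: float = 0.10,
                    sd_fraction: float = 0.18) -> HsmmModel:
    """Tie duration means to the estimated cycle length via fixed state fractions."""
    means_s = np.array([
        s1_duration_s,
        systole_fraction * cycle_s - s1_duration_s,
        s2_duration_s,
        (1.0 - systole_fraction) * cycle_s - s2_duration_s,
    ])
    if np.any(means_s <= 0):
        raise ValueError("cycle length too short for the configured component durations")
    mean = means_s * feature_rate_hz
    sd = np.maximum(0.7, sd_fraction * mean)
    dmin = np.maximum(1, np.floor(mean - 3 * sd)).astype(int)
    dmax = np.ceil(mean + 3 * sd).astype(int)
    return HsmmModel(emissions, mean, sd, dmin, dmax, feature_rate_hz)


def viterbi_decode(features: EnvelopeFeatures, model: HsmmModel) -> SegmentationResult:
    """Duration-dependent Viterbi over the deterministic four-state cycle.

    Ties are broken toward the shorter duration, then the earlier state in
    cyclic order, so decoding is fully deterministic.
    """
    B = model.emissions.log_posteriors(features)
    if B.shape[1] != N_STATES:
        raise ValueError("emission/model dimension mismatch")
    T = B.shape[0]
    log_pmf = model.duration_log_pmf()
    log_surv = model.duration_log_survivor()
    # cumulative emission scores: run [a, t] for state s = C[t+1, s] - C[a, s]
    C = np.vstack([np.zeros(N_STATES), np.cumsum(B, axis=0)])

    delta = np.full((T, N_STATES), _NEG_INF)
    psi = np.zeros((T, N_STATES), dtype=int)
    for t in range(T):
        last = t == T - 1
        for s in range(N_STATES):
            dmax = min(int(model.dur_max[s]), t + 1)
            best, best_d = _NEG_INF, 0
            for d in range(1, dmax + 1):
                start = t - d + 1
                if start == 0:
                    prev = _LOG_QUARTER
                    dur_term = log_surv[s][d - 1]
                else:
                    prev = delta[start - 1, (s - 1) % N_STATES]
                    if prev == _NEG_INF:
                        continue
                    dur_term = log_surv[s][d - 1] if last else log_pmf[s][d - 1]
                score = prev + (C[t + 1, s] - C[start, s]) + dur_term
                if score > best:
                    best, best_d = score, d
            delta[t, s], psi[t, s] = best, best_d

    s_best, score = 0, delta[T - 1, 0]
    for s in range(1, N_STATES):
        if delta[T - 1, s] > score:
            s_best, score = s, delta[T - 1, s]
    if not np.isfinite(score):
        raise ValueError("no feasible state/duration path (durations too restrictive)")

    path = np.empty(T, dtype=int)
    t, s = T - 1, s_best
    while t >= 0:
        d = psi[t, s]
        path[t - d + 1:t + 1] = s
        t -= d
        s = (s - 1) % N_STATES
    starts = np.concatenate(([0], np.flatnonzero(np.diff(path) != 0) + 1))
    s1_onsets = starts[path[starts] == 0] / model.feature_rate_hz
    return SegmentationResult(path, s1_onsets, float(score), model.feature_rate_hz)


def mark_s1_onsets(recording: PcgRecording, emissions: EmissionModel,
                   feature_rate_hz: float = 50.0,
                   s1_duration_s: float = 0.12, s2_duration_s: float = 0.10,
                   ) -> SegmentationResult:
    """Full segmentation chain: features -> heart rate -> durations -> decode."""
    feats = extract_envelope_features(recording, feature_rate_hz)
    cycle_s, systole_fraction = estimate_heart_rate(feats)
    model = adapt_durations(emissions, cycle_s, systole_fraction, feature_rate_hz,
                            s1_duration_s, s2_duration_s)
    return viterbi_decode(feats, model)
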