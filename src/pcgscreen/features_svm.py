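"""Hand-crafted feature bank, Tamhane's T2 feature screening and an RBF SVM.

The feature bank is a documented generic set for heart-sound frames:
energy, low/high band-energy ratio, zero-crossing rate, spectral centroid
and bandwidth, sample entropy, wavelet-band energies and Mel-cepstral
summary statistics.  Features are screened across the three classes with
Tamhane's T2 procedure -- all pairwise Welch-type t comparisons with a
Sidak multiplicity adjustment -- and the survivors (capped at the three
smallest adjusted P by default) feed a one-vs-one RBF SVM tuned by grid
search on the training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy.fft import dct
from scipy.signal import periodogram
from scipy.stats import t as t_dist
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .framing import FrameDataset

#: grid-search ranges: C in 2^-5 .. 2^15, gamma in 2^-15 .. 2^3, powers of 4
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 4))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 4))


def _spectral_moments(x: np.ndarray, fs: float) -> tuple[float, float, float]:
    f, pxx = periodogram(x, fs=fs)
    total = pxx.sum()
    if total <= 0:
        return 0.0, 0.0, 0.0
    centroid = float((f * pxx).sum() / total)
    bandwidth = float(np.sqrt(((f - centroid) ** 2 * pxx).sum() / total))
    low = pxx[(f >= 10) & (f < 90)].sum()
    high = pxx[(f >= 90) & (f <= 250)].sum()
    ratio = float(low / (high + 1e-12))
    return centroid, bandwidth, ratio


def _zero_crossing_rate(x: np.ndarray) -> float:
    c = x - x.mean()
    s = np.sign(c)
    s[s == 0] = 1
    return float(np.mean(np.abs(np.diff(s)) > 0))


def _sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2,
                    max_len: int = 240) -> float:
    """SampEn(m, r = r_frac * sd); constant signals return 0 by convention."""
    if x.size > max_len:  # decimate: SampEn is O(n^2)
        x = x[:: int(np.ceil(x.size / max_len))]
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_frac * sd
    n = x.size

    def count(mm: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
        iu = np.triu_indices(d.shape[0], k=1)
        return int((d[iu] <= r).sum())

    b, a = count(m), count(m + 1)
    if a == 0 or b == 0:
        return 0.0
    return float(-np.log(a / b))


def _wavelet_energies(x: np.ndarray, wavelet: str = "db4", level: int = 4) -> np.ndarray:
    coeffs = pywt.wavedec(x, wavelet, level=level)
    e = np.array([np.sum(c**2) for c in coeffs])
    return e / (e.sum() + 1e-12)


def _mel_filterbank(n_filters: int, n_fft: int, fs: float, f_max: float) -> np.ndarray:
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    mels = np.linspace(0, hz_to_mel(f_max), n_filters + 2)
    hz = mel_to_hz(mels)
    bins = np.floor((n_fft + 1) * hz / fs).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        l, c, r = bins[i], bins[i + 1], bins[i + 2]
        for k in range(l, c):
            fb[i, k] = (k - l) / max(c - l, 1)
        for k in range(c, r):
            fb[i, k] = (r - k) / max(r - c, 1)
    return fb


def _mfcc_summary(x: np.ndarray, fs: float, n_coef: int = 5,
                  win: int = 128) -> np.ndarray:
    """Mean of the first cepstral coefficients over short windows."""
    n_win = x.size // win
    if n_win == 0:
        return np.zeros(n_coef)
    fb = _mel_filterbank(16, win, fs, min(fs / 2, 300.0))
    frames = x[: n_win * win].reshape(n_win, win)
    spec = np.abs(np.fft.rfft(frames * np.hanning(win), axis=1)) ** 2
    mel = np.log(spec @ fb.T + 1e-10)
    ceps = dct(mel, type=2, norm="ortho", axis=1)[:, :n_coef]
    return ceps.mean(axis=0)


def extract_features(dataset: FrameDataset) -> pd.DataFrame:
    """Deterministic per-frame feature table; last column is ``class_label``."""
    fs = dataset.target_rate_hz
    rows = []
    for frame in dataset.frames:
        x = frame.values
        centroid, bandwidth, ratio = _spectral_moments(x - x.mean(), fs)
        wave = _wavelet_energies(x)
        mfcc = _mfcc_summary(x, fs)
        row = {
            "energy": float(np.mean((x - x.mean()) ** 2)),
            "band_ratio_low_high": ratio,
            "zero_crossing_rate": _zero_crossing_rate(x),
            "spectral_centroid_hz": centroid,
            "spectral_bandwidth_hz": bandwidth,
            "sample_entropy": _sample_entropy(x),
        }
        row.update({f"wavelet_energy_{i}": float(v) for i, v in enumerate(wave)})
        row.update({f"mfcc_{i + 1}": float(v) for i, v in enumerate(mfcc)})
        row["class_label"] = frame.class_label
        rows.append(row)
    df = pd.DataFrame(rows)
    feat = df.drop(columns="class_label")
    if not np.isfinite(feat.to_numpy()).all():
        raise AssertionError("feature table contains non-finite values")
    return df


@dataclass
class SelectionReport:
    pairwise: pd.DataFrame        # feature, group_a, group_b, t, df, p_adj
    feature_p: pd.Series          # per feature: smallest adjusted pairwise P
    selected: list[str]
    alpha: float


def tamhane_t2_select(table: pd.DataFrame, alpha: float = 0.001,
                      cap: int | None = 3) -> SelectionReport:
    """Screen features by Tamhane's T2 across the class groups.

    For each feature and each group pair the Welch t statistic

        t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b)

    is referred to a t distribution with Welch-Satterthwaite degrees of
    freedom, and the two-sided P is Sidak-adjusted for the k = 3 pairs:
    p_adj = 1 - (1 - p)^k.  A feature is selected when its smallest
    adjusted P is below ``alpha``; ``cap`` keeps the best few (default 3).
    """
    labels = table["class_label"]
    groups = sorted(labels.unique())
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"class {g!r} has fewer than 2 observations")
    feats = [c for c in table.columns if c != "class_label"]
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    k = len(pairs)
    rows = []
    for feat in feats:
        for a, b in pairs:
            xa = table.loc[labels == a, feat].to_numpy()
            xb = table.loc[labels == b, feat].to_numpy()
            va = xa.var(ddof=1) / xa.size + 1e-24
            vb = xb.var(ddof=1) / xb.size + 1e-24
            t_stat = (xa.mean() - xb.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (xa.size - 1) + vb**2 / (xb.size - 1))
            p = 2 * t_dist.sf(abs(t_stat), df)
            p_adj = 1.0 - (1.0 - p) ** k
            rows.append((feat, a, b, float(t_stat), float(df), float(p), float(p_adj)))
    pairwise = pd.DataFrame(rows, columns=["feature", "group_a", "group_b",
                                           "t", "df", "p", "p_adj"])
    feature_p = pairwise.groupby("feature", sort=False)["p_adj"].min()
    hits = feature_p[feature_p < alpha].sort_values()
    selected = list(hits.index[:cap]) if cap is not None else list(hits.index)
    return SelectionReport(pairwise, feature_p, selected, alpha)


@dataclass
class SvmModel:
    pipeline: Pipeline
    selected: list[str]
    C: float
    gamma: float
    cv_scores: pd.DataFrame


def train_svm(table: pd.DataFrame, selected: list[str], seed: int = 0,
              c_grid: tuple[float, ...] = DEFAULT_C_GRID,
              gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
              n_inner_folds: int = 3) -> SvmModel:
    """Standardize selected features and grid-search a one-vs-one RBF SVM.

    The (C, gamma) pair with the best internal cross-validated accuracy on
    the supplied (training) table wins; ties go to the first grid point, so
    the choice is deterministic for a fixed seed.
    """
    if not selected:
        raise ValueError("no features selected; cannot train the SVM")
    y = table["class_label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    X = table[selected].to_numpy()
    skf = StratifiedKFold(n_splits=n_inner_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    scores = []
    best = (-1.0, None)
    for C in c_grid:
        for gamma in gamma_grid:
            accs = []
            for tr, te in splits:
                pipe = Pipeline([("scale", StandardScaler()),
                                 ("svc", SVC(kernel="rbf", C=C, gamma=gamma,
                                             decision_function_shape="ovo"))])
                pipe.fit(X[tr], y[tr])
                accs.append(float((pipe.predict(X[te]) == y[te]).mean()))
            mean_acc = float(np.mean(accs))
            scores.append((C, gamma, mean_acc))
            if mean_acc > best[0]:
                best = (mean_acc, (C, gamma))
    C, gamma = best[1]
    final = Pipeline([("scale", StandardScaler()),
                      ("svc", SVC(kernel="rbf", C=C, gamma=gamma,
                                  decision_function_shape="ovo"))])
    final.fit(X, y)
    return SvmModel(final, list(selected), C, gamma,
                    pd.DataFrame(scores, columns=["C", "gamma", "cv_accuracy"]))


def predict_svm(model: SvmModel, table: pd.DataFrame) -> np.ndarray:
    return model.pipeline.predict(table[model.selected].to_numpy())
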