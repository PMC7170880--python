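"""Hand-engineered EEG features and the classical LR/RF baselines.

Per-channel time-domain block: mean, variance, skewness, kurtosis
(standardized 3rd/4th central moments; kurtosis is *non-excess*, so a
Gaussian scores ~3; constant channels score 0 by convention), total signal
area (sum |x| dt), peak-to-peak, strict zero-crossing count after mean
removal, and decorrelation time (lag of the first zero crossing of the
autocorrelation, linearly interpolated).

Per-channel frequency block: total spectral energy (Parseval-consistent with
the time-domain sum of squares), fractional energies of the fundamental
rhythmic bands (delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30, gamma
30-70 Hz), and DWT detail-coefficient energies (Daubechies-4, 5 levels).

Connectivity block: for each of the 171 unordered electrode pairs, the
maximum over +-0.5 s lags of the absolute normalized cross-correlation.

Graph block: threshold the connectivity matrix (default 0.7) into an
undirected electrode graph; report per-node degree and clustering
coefficient and the graph's global efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pywt
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from weakeeg.clips import Clip
from weakeeg.errors import EmptyClassError
from weakeeg.records import MONTAGE_1020, N_CHANNELS

#: Fundamental rhythmic bands (Hz), standard clinical definitions.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 70.0),
}
DWT_WAVELET = "db4"
DWT_LEVELS = 5
XCORR_MAX_LAG_S = 0.5
GRAPH_THRESHOLD = 0.7

TIME_FEATURES = ("mean", "variance", "skewness", "kurtosis", "total_area",
                 "peak_to_peak", "zero_crossings", "decorrelation_time_s")


def _as_array(clip: Clip | np.ndarray) -> np.ndarray:
    x = clip.x if isinstance(clip, Clip) else np.asarray(clip)
    if x.ndim != 2:
        raise ValueError("expected a (n_samples, n_channels) matrix")
    return np.asarray(x, dtype=np.float64)


def decorrelation_time(x: np.ndarray, fs: float) -> float:
    """Lag (s) of the first zero crossing of the autocorrelation function."""
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return 0.0
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[:n] / denom
    below = np.nonzero(acf <= 0)[0]
    if len(below) == 0:
        return (n - 1) / fs
    k = int(below[0])
    if k == 0:
        return 0.0
    # linear interpolation between the last positive lag and the crossing
    a, b = acf[k - 1], acf[k]
    frac = a / (a - b) if a != b else 0.0
    return (k - 1 + frac) / fs


def time_domain_features(clip: Clip | np.ndarray, fs: float = 200.0) -> np.ndarray:
    """(n_channels, 8) time-domain block; see module docstring for conventions."""
    x = _as_array(clip)
    n_ch = x.shape[1]
    out = np.zeros((n_ch, len(TIME_FEATURES)))
    centered = x - x.mean(axis=0, keepdims=True)
    var = x.var(axis=0)
    out[:, 0] = x.mean(axis=0)
    out[:, 1] = var
    nondeg = var > 0
    if nondeg.any():
        out[nondeg, 2] = stats.skew(x[:, nondeg], axis=0)
        out[nondeg, 3] = stats.kurtosis(x[:, nondeg], axis=0, fisher=False)
    out[:, 4] = np.abs(x).sum(axis=0) / fs
    out[:, 5] = x.max(axis=0) - x.min(axis=0)
    out[:, 6] = np.count_nonzero(centered[:-1] * centered[1:] < 0, axis=0)
    for c in range(n_ch):
        out[c, 7] = decorrelation_time(x[:, c], fs) if nondeg[c] else 0.0
    return out


def frequency_domain_features(
    clip: Clip | np.ndarray,
    fs: float = 200.0,
    bands: dict[str, tuple[float, float]] = BANDS,
    wavelet: str = DWT_WAVELET,
    dwt_levels: int = DWT_LEVELS,
) -> np.ndarray:
    """(n_channels, 1 + n_bands + dwt_levels) spectral block.

    Total energy is ``sum |X_k|^2 / N`` over the full DFT, equal to the
    time-domain sum of squares by Parseval; band fractions are band energy
    over total (0 for an all-zero channel).
    """
    x = _as_array(clip)
    n, n_ch = x.shape
    spec = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # full-spectrum weights: every rfft bin except DC and Nyquist appears twice
    w = np.full(len(freqs), 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    power = w[:, None] * np.abs(spec) ** 2 / n
    total = power.sum(axis=0)

    out = np.zeros((n_ch, 1 + len(bands) + dwt_levels))
    out[:, 0] = total
    safe_total = np.where(total > 0, total, 1.0)
    for j, (lo, hi) in enumerate(bands.values()):
        mask = (freqs >= lo) & (freqs < hi)
        out[:, 1 + j] = power[mask].sum(axis=0) / safe_total * (total > 0)

    coeffs = pywt.wavedec(x, wavelet, level=dwt_levels, axis=0)
    for lvl, detail in enumerate(coeffs[1:]):  # details, coarsest first
        out[:, 1 + len(bands) + lvl] = (detail**2).sum(axis=0)
    return out


def connectivity_features(
    clip: Clip | np.ndarray, fs: float = 200.0, max_lag_s: float = XCORR_MAX_LAG_S
) -> np.ndarray:
    """Condensed (n_pairs,) vector of max |normalized cross-correlation|.

    The lag search covers +-``max_lag_s``; a pair with a zero-variance
    channel scores 0.  Pairs follow ``np.triu_indices`` order over the
    channel axis.
    """
    x = _as_array(clip)
    n, n_ch = x.shape
    x = x - x.mean(axis=0, keepdims=True)
    norms = np.sqrt((x**2).sum(axis=0))
    max_lag = int(round(max_lag_s * fs))
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft, axis=0)
    iu, ju = np.triu_indices(n_ch, k=1)
    out = np.zeros(len(iu))
    for p, (i, j) in enumerate(zip(iu, ju)):
        if norms[i] == 0 or norms[j] == 0:
            continue
        cc = np.fft.irfft(spec[:, i] * np.conj(spec[:, j]), nfft)
        lagged = np.concatenate([cc[-max_lag:], cc[: max_lag + 1]])
        out[p] = np.abs(lagged).max() / (norms[i] * norms[j])
    return np.minimum(out, 1.0)


def connectivity_matrix(clip: Clip | np.ndarray, fs: float = 200.0) -> np.ndarray:
    """(n_ch, n_ch) symmetric matrix form of :func:`connectivity_features`."""
    x = _as_array(clip)
    n_ch = x.shape[1]
    vec = connectivity_features(clip, fs)
    mat = np.zeros((n_ch, n_ch))
    iu, ju = np.triu_indices(n_ch, k=1)
    mat[iu, ju] = vec
    mat[ju, iu] = vec
    return mat


def graph_features(
    clip: Clip | np.ndarray, fs: float = 200.0, threshold: float = GRAPH_THRESHOLD
) -> np.ndarray:
    """(2 * n_ch + 1,) block: per-node degree, clustering, global efficiency."""
    mat = connectivity_matrix(clip, fs)
    n_ch = mat.shape[0]
    adj = mat >= threshold
    np.fill_diagonal(adj, False)
    g = nx.from_numpy_array(adj.astype(int))
    degrees = np.array([g.degree[i] for i in range(n_ch)], dtype=float)
    clustering = np.array([nx.clustering(g, i) for i in range(n_ch)], dtype=float)
    efficiency = nx.global_efficiency(g) if g.number_of_edges() else 0.0
    return np.concatenate([degrees, clustering, [efficiency]])


def feature_names(n_ch: int = N_CHANNELS) -> list[str]:
    ch = MONTAGE_1020 if n_ch == N_CHANNELS else [f"ch{c}" for c in range(n_ch)]
    names = [f"{c}_{f}" for c in ch for f in TIME_FEATURES]
    freq = ["total_energy"] + [f"frac_{b}" for b in BANDS] + [
        f"dwt_d{lvl}" for lvl in range(1, DWT_LEVELS + 1)
    ]
    names += [f"{c}_{f}" for c in ch for f in freq]
    iu, ju = np.triu_indices(n_ch, k=1)
    names += [f"xcorr_{ch[i]}_{ch[j]}" for i, j in zip(iu, ju)]
    names += [f"{c}_degree" for c in ch] + [f"{c}_clustering" for c in ch]
    names += ["global_efficiency"]
    return names


def extract_features(clip: Clip | np.ndarray, fs: float = 200.0) -> np.ndarray:
    """Full flat feature vector for one clip (571 features for 19 channels)."""
    return np.concatenate([
        time_domain_features(clip, fs).ravel(),
        frequency_domain_features(clip, fs).ravel(),
        connectivity_features(clip, fs),
        graph_features(clip, fs),
    ])


def feature_matrix(clips: Sequence[Clip], fs: float = 200.0) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) design matrix over clips, rows in clip order."""
    X = np.stack([extract_features(c, fs) for c in clips])
    y = np.array([c.label for c in clips], dtype=np.int64)
    return X, y


@dataclass
class FittedBaseline:
    """A standardizer + classifier pair with a predict-probability surface."""

    model_kind: str
    scaler: StandardScaler
    clf: object

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(seizure) per row."""
        return self.clf.predict_proba(self.scaler.transform(X))[:, 1]


def fit_baseline(
    X: np.ndarray,
    y: np.ndarray,
    model: Literal["lr", "rf"] = "rf",
    seed: int = 0,
) -> FittedBaseline:
    """Fit the classical baseline on standardized features.

    RF: 100 trees, max depth 4 (the reference hyperparameters).  LR:
    L2-regularized with unit inverse-regularization strength (C=1.0).
    Standardization statistics come from the training set only.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise EmptyClassError("baseline fitting needs both classes present")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if model == "rf":
        clf = RandomForestClassifier(n_estimators=100, max_depth=4, random_state=seed)
    elif model == "lr":
        clf = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)  # L2 default
    else:
        raise ValueError(f"unknown baseline model {model!r}")
    clf.fit(Xs, y)
    return FittedBaseline(model, scaler, clf)
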