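"""Signal preprocessing and the 36-feature catalog for scratch windows.

Each 3-s tri-axial window is high-pass filtered (first-order Butterworth,
0.25 Hz cutoff) to remove gravity, then reduced to three one-dimensional
signals that are insensitive to device orientation:

* SVM -- signal vector magnitude of the filtered axes,
* PC1, PC2 -- first and second principal components of the filtered samples
  (the principal-component rotation is fit on the window itself).

Twelve time- and frequency-domain descriptors are computed per signal,
giving a fixed, ordered 36-feature vector per window.  The catalog centres
on measures of movement periodicity (mean cross rate, dominant frequency)
and smoothness (SPARC, jerk ratio), which separate the rapid, jerky
oscillations of scratching from slower, smoother restless repositioning.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

SIGNAL_NAMES = ("svm", "pc1", "pc2")

PER_SIGNAL_FEATURES = (
    "mean_cross_rate",
    "dominant_freq",
    "dominant_power_ratio",
    "spectral_entropy",
    "spectral_flatness",
    "sparc",
    "jerk_ratio",
    "rms",
    "range",
    "iqr",
    "skewness",
    "kurtosis",
)

#: Frozen, versioned feature order: 12 descriptors x (svm, pc1, pc2).
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{sig}_{feat}" for sig in SIGNAL_NAMES for feat in PER_SIGNAL_FEATURES
)
FEATURE_SET_VERSION = "1"

_EPS = 1e-12


def highpass_filter(
    arr: np.ndarray, fs: float = 20.0, cutoff: float = 0.25, order: int = 1
) -> np.ndarray:
    """First-order Butterworth IIR high-pass, applied causally along axis 0."""
    b, a = sps.butter(order, cutoff, btype="highpass", fs=fs)
    return sps.lfilter(b, a, np.asarray(arr, dtype=float), axis=0)


def preprocess_window(
    raw: np.ndarray, fs: float = 20.0, cutoff: float = 0.25
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Filter a raw (n, 3) window and derive the SVM, PC1 and PC2 signals.

    The PC rotation is fit on this window's filtered samples; each loading
    vector's largest-magnitude component is forced positive so the
    decomposition is deterministic.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 3:
        raise ValueError("raw window must be an (n, 3) array")
    filt = highpass_filter(raw, fs=fs, cutoff=cutoff)
    svm = np.linalg.norm(filt, axis=1)
    centered = filt - filt.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    scores = centered @ vt.T
    return svm, scores[:, 0], scores[:, 1]


def detect_hand_movement(
    raw: np.ndarray,
    fs: float = 20.0,
    cov_threshold: float = 0.023,
    subwindow_s: float = 0.5,
) -> bool:
    """Hand-movement gate on a raw acceleration window.

    The rolling coefficient of variation (SD / mean) of the acceleration
    vector magnitude is computed over ``subwindow_s`` sub-windows with a
    one-sample stride; the window counts as hand movement only when the CoV
    is strictly above ``cov_threshold`` in every sub-window (movement must be
    present for the entirety of the window).  A sub-window with (near-)zero
    mean magnitude has an undefined CoV and counts as no movement.
    """
    raw = np.asarray(raw, dtype=float)
    mag = np.linalg.norm(raw, axis=1)
    w = max(2, int(round(subwindow_s * fs)))
    if len(mag) < w:
        return False
    views = np.lib.stride_tricks.sliding_window_view(mag, w)
    means = views.mean(axis=1)
    sds = views.std(axis=1)
    if np.any(np.abs(means) < _EPS):
        return False
    cov = sds / means
    return bool(np.all(cov > cov_threshold))


def sparc(
    movement: np.ndarray,
    fs: float,
    padlevel: int = 4,
    fc: float = 10.0,
    amp_th: float = 0.05,
) -> float:
    """Spectral arc length smoothness of a movement intensity profile.

    The Fourier magnitude spectrum is max-normalised, restricted to
    frequencies below ``fc`` and to the band where the normalised amplitude
    exceeds ``amp_th``, and the negative arc length of the resulting curve is
    returned.  Smoother movement concentrates spectral mass at low frequency
    and yields a value of smaller magnitude (closer to zero is smoother in
    magnitude terms; the value itself is negative).
    """
    movement = np.asarray(movement, dtype=float)
    n = len(movement)
    if n == 0:
        return 0.0
    nfft = int(2 ** (np.ceil(np.log2(n)) + padlevel))
    f = np.arange(0, fs, fs / nfft)
    mf = np.abs(np.fft.fft(movement, nfft))
    peak = mf.max()
    if peak < _EPS:
        return 0.0
    mf = mf / peak
    sel = f <= fc
    f_sel, mf_sel = f[sel], mf[sel]
    above = np.flatnonzero(mf_sel >= amp_th)
    if above.size == 0:
        return 0.0
    f_sel = f_sel[above[0] : above[-1] + 1]
    mf_sel = mf_sel[above[0] : above[-1] + 1]
    if len(f_sel) < 2:
        return 0.0
    df = np.diff(f_sel) / (f_sel[-1] - f_sel[0])
    dm = np.diff(mf_sel)
    return float(-np.sum(np.sqrt(df**2 + dm**2)))


def _signal_features(x: np.ndarray, fs: float) -> list[float]:
    x = np.asarray(x, dtype=float)
    n = len(x)
    rms = float(np.sqrt(np.mean(x**2))) if n else 0.0
    rng = float(np.ptp(x)) if n else 0.0
    iqr = float(stats.iqr(x)) if n else 0.0
    if n < 3 or np.std(x) < _EPS:
        skew = 0.0
        kurt = 0.0
    else:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))

    centered = x - x.mean() if n else x
    if n > 1 and np.any(np.abs(centered) > _EPS):
        crossings = np.sum(np.signbit(centered[:-1]) != np.signbit(centered[1:]))
        mean_cross_rate = float(crossings) * fs / n
    else:
        mean_cross_rate = 0.0

    if n > 1 and rms > _EPS:
        jerk_ratio = float(np.sqrt(np.mean(np.diff(x) ** 2)) * fs / rms)
    else:
        jerk_ratio = 0.0

    if n > 3:
        f, pxx = sps.periodogram(x, fs=fs, detrend="constant")
        f, pxx = f[1:], pxx[1:]  # drop DC
        total = pxx.sum()
    else:
        total = 0.0
    if total > _EPS:
        k = int(np.argmax(pxx))
        dominant_freq = float(f[k])
        dominant_power_ratio = float(pxx[k] / total)
        p = pxx / total
        nz = p[p > _EPS]
        spectral_entropy = float(-(nz * np.log(nz)).sum() / np.log(len(p)))
        spectral_flatness = float(
            np.exp(np.mean(np.log(pxx + _EPS))) / (np.mean(pxx) + _EPS)
        )
    else:
        dominant_freq = 0.0
        dominant_power_ratio = 0.0
        spectral_entropy = 0.0
        spectral_flatness = 0.0

    sp = sparc(x, fs)

    return [
        mean_cross_rate,
        dominant_freq,
        dominant_power_ratio,
        spectral_entropy,
        spectral_flatness,
        sp,
        jerk_ratio,
        rms,
        rng,
        iqr,
        skew,
        kurt,
    ]


def extract_features(
    svm: np.ndarray, pc1: np.ndarray, pc2: np.ndarray, fs: float = 20.0
) -> np.ndarray:
    """36-feature vector (12 descriptors per signal, order ``FEATURE_NAMES``)."""
    if not (len(svm) == len(pc1) == len(pc2)):
        raise ValueError("signals must have equal length")
    out = []
    for sig in (svm, pc1, pc2):
        out.extend(_signal_features(np.asarray(sig, dtype=float), fs))
    return np.asarray(out, dtype=float)


class WindowFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform raw (n_windows, n_samples, 3) acceleration windows into
    the 36-column feature matrix.

    Stateless: ``fit`` only validates the input shape.
    """

    def __init__(self, fs: float = 20.0, cutoff: float = 0.25):
        self.fs = fs
        self.cutoff = cutoff

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 3:
            raise ValueError("X must have shape (n_windows, n_samples, 3)")
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 3:
            raise ValueError("X must have shape (n_windows, n_samples, 3)")
        out = np.empty((X.shape[0], len(FEATURE_NAMES)))
        for i, win in enumerate(X):
            svm, pc1, pc2 = preprocess_window(win, fs=self.fs, cutoff=self.cutoff)
            out[i] = extract_features(svm, pc1, pc2, fs=self.fs)
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES, dtype=object)
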