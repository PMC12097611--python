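"""Time-series feature catalogue for fTCD velocity envelopes.

A fixed, versioned catalogue of statistical, temporal and spectral
descriptors computed on each side's envelope; the left and right vectors
are concatenated side-major.  Degenerate inputs (constant envelopes) yield
well-defined zeros, never NaN, so downstream screening always sees a
complete matrix.

Catalogue "v1", per side (47 features):

* statistical — mean, variance, skewness, kurtosis, median absolute
  deviation, interquartile range, 10 relative histogram counts over the
  signal's range, ECDF percentiles 5/25/50/75/95;
* temporal — autocorrelation at lags 1-5, zero-crossing rate of the
  mean-removed signal, peak count, mean peak-to-peak amplitude, mean slope,
  line length, sample entropy (m=2, r=0.2 sd);
* spectral — total power, spectral centroid, spectral spread, 85% roll-off
  frequency, power in the cardiac band 0.7-2 Hz, and per-level energies and
  coefficient spreads of a 4-level db4 wavelet decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
import scipy.signal
import scipy.stats

from .envelope import EnvelopeSignal

__all__ = [
    "CATALOGUE_VERSION",
    "EnvelopeFeatureVector",
    "feature_names",
    "extract_envelope_features",
    "ranksum_select",
]

CATALOGUE_VERSION = "v1"
_N_HIST_BINS = 10
_ACF_LAGS = (1, 2, 3, 4, 5)
_ECDF_PERCENTILES = (5, 25, 50, 75, 95)
_WAVELET = "db4"
_DWT_LEVELS = 4
_CARDIAC_BAND = (0.7, 2.0)


@dataclass
class EnvelopeFeatureVector:
    """Feature values with aligned names and the catalogue version tag."""

    values: np.ndarray
    names: list[str]
    catalogue_version: str = CATALOGUE_VERSION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


def _side_names() -> list[str]:
    names = ["mean", "variance", "skewness", "kurtosis", "mad", "iqr"]
    names += [f"hist_bin{i}" for i in range(_N_HIST_BINS)]
    names += [f"ecdf_p{p}" for p in _ECDF_PERCENTILES]
    names += [f"acf_lag{k}" for k in _ACF_LAGS]
    names += ["zero_cross_rate", "peak_count", "mean_peak_to_peak",
              "mean_slope", "line_length", "sample_entropy"]
    names += ["total_power", "spectral_centroid", "spectral_spread",
              "rolloff_85", "cardiac_band_power"]
    names += [f"dwt_energy_l{k}" for k in range(_DWT_LEVELS + 1)]
    names += [f"dwt_std_l{k}" for k in range(_DWT_LEVELS + 1)]
    return names


def feature_names(sides: tuple[str, ...] = ("left", "right")) -> list[str]:
    """Full catalogue names, side-major (``left_mean``, ..., ``right_mean``, ...)."""
    return [f"{side}_{n}" for side in sides for n in _side_names()]


def _sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """SampEn(m, r) with r = r_frac * sd; 0 for degenerate signals."""
    sd = x.std()
    n = x.size
    if sd == 0 or n <= m + 1:
        return 0.0
    r = r_frac * sd
    # template matches built incrementally: C[i, j] says windows starting at
    # i and j agree within r on every sample compared so far (Chebyshev)
    D = np.abs(x[:, None] - x[None, :]) <= r
    C = D
    for k in range(1, m):
        C = C[:-1, :-1] & D[k:, k:]
    b = int(np.triu(C, k=1).sum())
    C = C[:-1, :-1] & D[m:, m:]
    a = int(np.triu(C, k=1).sum())
    if a == 0 or b == 0:
        return 0.0
    return float(-np.log(a / b))


def _autocorr(x: np.ndarray, lag: int) -> float:
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom == 0 or lag >= x.size:
        return 0.0
    return float(np.dot(xc[:-lag], xc[lag:]) / denom)


def _spectral_block(x: np.ndarray, fs: float) -> list[float]:
    xc = x - x.mean()
    psd = np.abs(np.fft.rfft(xc)) ** 2 / x.size
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    total = psd.sum()
    if total == 0:
        centroid = spread = rolloff = cardiac = 0.0
    else:
        w = psd / total
        centroid = float(np.sum(freqs * w))
        spread = float(np.sqrt(np.sum((freqs - centroid) ** 2 * w)))
        cum = np.cumsum(psd)
        rolloff = float(freqs[np.searchsorted(cum, 0.85 * total)])
        band = (freqs >= _CARDIAC_BAND[0]) & (freqs <= _CARDIAC_BAND[1])
        cardiac = float(psd[band].sum())
    out = [float(total), centroid, spread, rolloff, cardiac]

    level = min(_DWT_LEVELS, pywt.dwt_max_level(x.size, _WAVELET))
    coeffs = pywt.wavedec(xc, _WAVELET, level=max(level, 1))
    energies = [float(np.sum(c**2)) for c in coeffs]
    spreads = [float(np.std(c)) for c in coeffs]
    # pad to the fixed catalogue width if the signal was too short for 4 levels
    energies += [0.0] * (_DWT_LEVELS + 1 - len(energies))
    spreads += [0.0] * (_DWT_LEVELS + 1 - len(spreads))
    out += energies[: _DWT_LEVELS + 1] + spreads[: _DWT_LEVELS + 1]
    return out


def _side_features(v: np.ndarray, frame_rate: float) -> list[float]:
    v = np.asarray(v, dtype=float)
    out: list[float] = []
    sd = v.std()
    constant = sd == 0

    # statistical
    out += [float(v.mean()), float(v.var())]
    out += [0.0, 0.0] if constant else [
        float(scipy.stats.skew(v)), float(scipy.stats.kurtosis(v))
    ]
    out += [float(scipy.stats.median_abs_deviation(v)), float(np.subtract(*np.percentile(v, [75, 25])))]
    lo, hi = v.min(), v.max()
    if hi == lo:
        counts = np.zeros(_N_HIST_BINS)
        counts[0] = 1.0
    else:
        counts, _ = np.histogram(v, bins=_N_HIST_BINS, range=(lo, hi))
        counts = counts / v.size
    out += [float(c) for c in counts]
    out += [float(p) for p in np.percentile(v, _ECDF_PERCENTILES)]

    # temporal
    out += [_autocorr(v, k) for k in _ACF_LAGS]
    vc = v - v.mean()
    zcr = 0.0 if constant else float(np.mean(np.signbit(vc[:-1]) != np.signbit(vc[1:])))
    out.append(zcr)
    if constant:
        out += [0.0, 0.0]
    else:
        peaks, _ = scipy.signal.find_peaks(v)
        troughs, _ = scipy.signal.find_peaks(-v)
        p2p = 0.0
        if peaks.size and troughs.size:
            p2p = float(v[peaks].mean() - v[troughs].mean())
        out += [float(peaks.size), p2p]
    dv = np.diff(v)
    out.append(float(dv.mean() * frame_rate) if dv.size else 0.0)  # mean slope, units/s
    out.append(float(np.abs(dv).sum()))  # line length
    out.append(_sample_entropy(v))

    # spectral
    out += _spectral_block(v, frame_rate)
    return out


def extract_envelope_features(
    envelopes: EnvelopeSignal | tuple[EnvelopeSignal, ...] | list[EnvelopeSignal],
    catalogue: str = CATALOGUE_VERSION,
) -> EnvelopeFeatureVector:
    """Deterministic feature vector for one trial's envelope(s).

    Accepts a single :class:`EnvelopeSignal` or the (left, right) pair; with
    a pair, per-side vectors are concatenated side-major.  Envelopes must be
    at least 32 frames long.
    """
    if catalogue != CATALOGUE_VERSION:
        raise ValueError(f"unknown catalogue version: {catalogue!r}")
    if isinstance(envelopes, EnvelopeSignal):
        envelopes = (envelopes,)
    values: list[float] = []
    names: list[str] = []
    for env in envelopes:
        if env.velocity.size < 32:
            raise ValueError("envelope shorter than 32 frames")
        values += _side_features(env.velocity, env.frame_rate)
        names += [f"{env.side}_{n}" for n in _side_names()]
    return EnvelopeFeatureVector(values=np.asarray(values), names=names, catalogue_version=catalogue)


def ranksum_select(
    features: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Two-sided Wilcoxon rank-sum screening of a trials x features matrix.

    P-values use the exact null distribution when the combined sample size
    is at most 20 and the feature has no cross-class ties, and the normal
    approximation with midrank tie correction otherwise.  Returns
    ``(selected_indices, p_values, fallback)``: features with ``p < alpha``;
    if none pass, the single lowest-p feature is kept so the fTCD evidence
    stream never runs empty, and ``fallback`` is set.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"rank-sum screening needs exactly 2 classes, got {list(classes)}")
    a, b = X[labels == classes[0]], X[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 trials")
    n_comb = len(a) + len(b)
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        x, y = a[:, j], b[:, j]
        pooled = np.concatenate([x, y])
        if np.unique(pooled).size == 1:
            pvals[j] = 1.0  # complete ties carry no information
            continue
        has_ties = np.unique(pooled).size < n_comb
        if n_comb <= 20 and not has_ties:
            res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        else:
            # plain normal approximation with midrank tie correction; no
            # continuity correction, which is visibly conservative at the
            # trial counts screened here
            res = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            )
        pvals[j] = res.pvalue
    selected = np.flatnonzero(pvals < alpha)
    fallback = False
    if selected.size == 0:
        selected = np.array([int(np.argmin(pvals))])
        fallback = True
    return selected, pvals, fallback
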