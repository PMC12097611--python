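"""Filter-bank common spatial patterns (FBCSP) for two-class EEG trials.

The EEG feature extractor decomposes each trial into non-overlapping
frequency bands (2-60 Hz split into nine 6.5 Hz bands by default), and in
each band learns common-spatial-pattern (CSP) filters: directions ``w`` that
maximize the variance of one class while minimizing the other's.  With
trace-normalized trial covariances ``C = E E^T / tr(E E^T)`` and class-mean
covariances ``S+``, ``S-``, the filters solve the generalized eigenproblem

    S+ w = lambda (S+ + S-) w,

equivalently a simultaneous diagonalization ``W^T S+ W = L+``,
``W^T S- W = L-`` with ``L+ + L- = I``.  The per-trial feature is the log
variance of the signal projected on the ``n_pairs`` most discriminative
filters from each end of the eigenvalue spectrum, concatenated band-major
into a ``n_bands * 2 * n_pairs`` vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal

from .containers import TrialTensor

__all__ = [
    "FilterBankSpec",
    "SpatialFilterModel",
    "FBCSPModel",
    "build_filter_bank",
    "apply_filter_bank",
    "trial_covariance",
    "class_mean_covariance",
    "fit_csp",
    "csp_log_variance",
    "fbcsp_fit",
    "fbcsp_transform",
]

#: default ridge mixed into class covariances before the eigensolve
COV_REGULARIZATION = 1e-6


@dataclass(frozen=True)
class FilterBankSpec:
    """Non-overlapping band-pass filter bank.

    ``band_edges`` is an ordered tuple of ``(low, high)`` pairs in Hz.
    Filters are Butterworth of order ``filter_order``, applied
    forward-backward (zero phase) when ``zero_phase`` is set.
    """

    band_edges: tuple[tuple[float, float], ...]
    filter_order: int = 4
    design: str = "butterworth"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.design != "butterworth":
            raise ValueError(f"unsupported filter design: {self.design}")
        edges = np.asarray(self.band_edges, dtype=float)
        if edges.ndim != 2 or edges.shape[1] != 2 or edges.shape[0] < 1:
            raise ValueError("band_edges must be a non-empty list of (low, high) pairs")
        flat = edges.reshape(-1)
        if np.any(np.diff(flat) < 0) or np.any(edges[:, 0] >= edges[:, 1]):
            raise ValueError("bands must be non-overlapping and strictly increasing")
        if edges[0, 0] <= 0:
            raise ValueError("lowest band edge must be > 0")

    @property
    def n_bands(self) -> int:
        return len(self.band_edges)


def build_filter_bank(
    f_lo: float, f_hi: float, n_bands: int, bandwidth: float, **kwargs
) -> FilterBankSpec:
    """Partition ``[f_lo, f_hi]`` into ``n_bands`` contiguous bands.

    Band ``k`` spans ``[f_lo + k*bandwidth, f_lo + (k+1)*bandwidth]``; an
    upper edge that overshoots ``f_hi`` is clipped to ``f_hi`` (the default
    EEG bank is 9 x 6.5 Hz over 2-60 Hz, whose last band is clipped to
    [54, 60]).  A clipped band narrower than 1 Hz is rejected.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if f_lo <= 0 or bandwidth <= 0 or f_hi <= f_lo:
        raise ValueError("require 0 < f_lo < f_hi and bandwidth > 0")
    edges = []
    for k in range(n_bands):
        lo = f_lo + k * bandwidth
        hi = min(f_lo + (k + 1) * bandwidth, f_hi)
        if hi - lo < 1.0:
            raise ValueError(
                f"band {k} [{lo}, {hi}] narrower than 1 Hz after clipping to f_hi={f_hi}"
            )
        edges.append((lo, hi))
    return FilterBankSpec(band_edges=tuple(edges), **kwargs)


def default_eeg_bank() -> FilterBankSpec:
    """The standard 9-band, 6.5 Hz-wide bank over 2-60 Hz."""
    return build_filter_bank(2.0, 60.0, 9, 6.5)


def _band_sos(band: tuple[float, float], fs: float, order: int) -> np.ndarray:
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz at/above Nyquist ({fs / 2} Hz)")
    return scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def apply_filter_bank(trials: TrialTensor, spec: FilterBankSpec) -> list[TrialTensor]:
    """Band-pass filter every trial with each band of the bank.

    Returns one :class:`TrialTensor` per band with unchanged shape.  With
    ``zero_phase`` the filter runs forward-backward (``sosfiltfilt``), so
    the output has no group delay and trials stay time-aligned.
    """
    out = []
    for band in spec.band_edges:
        sos = _band_sos(band, trials.fs, spec.filter_order)
        if spec.zero_phase:
            filtered = scipy.signal.sosfiltfilt(sos, trials.data, axis=-1)
        else:
            filtered = scipy.signal.sosfilt(sos, trials.data, axis=-1)
        out.append(
            TrialTensor(
                data=filtered,
                fs=trials.fs,
                labels=trials.labels,
                channel_names=trials.channel_names,
            )
        )
    return out


def trial_covariance(trial: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance ``E E^T / tr(E E^T)`` of one trial."""
    E = np.asarray(trial, dtype=float)
    if E.ndim != 2:
        raise ValueError("trial must be a (channels, samples) matrix")
    S = E @ E.T
    tr = np.trace(S)
    if tr <= 0:
        raise ValueError("zero-trace trial (all-zero signal)")
    return S / tr


def class_mean_covariance(
    trials: TrialTensor | np.ndarray, labels: np.ndarray, class_tag
) -> np.ndarray:
    """Arithmetic mean of trace-normalized covariances over one class."""
    data = trials.data if isinstance(trials, TrialTensor) else np.asarray(trials)
    labels = np.asarray(labels)
    mask = labels == class_tag
    if not np.any(mask):
        raise ValueError(f"class {class_tag!r} absent from labels")
    covs = [trial_covariance(E) for E in data[mask]]
    return np.mean(covs, axis=0)


@dataclass
class SpatialFilterModel:
    """One band's CSP solution.

    ``W`` holds spatial filters in its columns, sorted by descending
    positive-class eigenvalue ``eigvals_pos``; ``W^T (S+ + S-) W = I`` and
    each ``lambda+ = w^T S+ w`` lies in [0, 1] with ``lambda+ + lambda- = 1``.
    """

    W: np.ndarray
    eigvals_pos: np.ndarray
    class_order: tuple

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]


def _well_conditioned(total: np.ndarray, cond_limit: float = 1e10) -> bool:
    try:
        scipy.linalg.cholesky(total)
    except scipy.linalg.LinAlgError:
        return False
    return np.linalg.cond(total) < cond_limit


def _check_symmetric(M: np.ndarray, name: str) -> None:
    scale = max(np.abs(M).max(), 1.0)
    if not np.allclose(M, M.T, atol=1e-10 * scale):
        raise ValueError(f"{name} is not symmetric")


def fit_csp(
    sigma_pos: np.ndarray,
    sigma_neg: np.ndarray,
    class_order: tuple = ("+", "-"),
    regularization: float | None = None,
) -> SpatialFilterModel:
    """Solve the two-class CSP generalized eigenproblem.

    Both inputs are symmetric PSD class-mean covariances.  When the
    composite ``S+ + S-`` is rank-deficient or severely ill-conditioned —
    typical for narrowly band-filtered trials — each covariance is ridge-
    regularized as ``(1-g) S + g (tr(S)/n) I`` with ``g = 1e-6`` before the
    eigensolve; well-conditioned problems are solved exactly so the
    whitening identities hold to machine precision.  Pass an explicit
    ``regularization`` to force a ridge.

    Eigenvector sign is fixed so each column's largest-magnitude entry is
    positive, and equal eigenvalues keep their original solver order
    (stable sort), making the output deterministic across LAPACK backends.
    """
    sigma_pos = np.asarray(sigma_pos, dtype=float)
    sigma_neg = np.asarray(sigma_neg, dtype=float)
    if sigma_pos.shape != sigma_neg.shape or sigma_pos.ndim != 2:
        raise ValueError("covariances must be square matrices of equal shape")
    _check_symmetric(sigma_pos, "sigma_pos")
    _check_symmetric(sigma_neg, "sigma_neg")
    n = sigma_pos.shape[0]

    def _reg(S: np.ndarray, g: float) -> np.ndarray:
        return (1.0 - g) * S + g * (np.trace(S) / n) * np.eye(n)

    if regularization is None:
        gamma = 0.0 if _well_conditioned(sigma_pos + sigma_neg) else COV_REGULARIZATION
    else:
        gamma = regularization
    sp = _reg(sigma_pos, gamma)
    sn = _reg(sigma_neg, gamma)
    total = sp + sn
    # definiteness check of the composite matrix
    try:
        scipy.linalg.cholesky(total)
    except scipy.linalg.LinAlgError as err:
        raise ValueError("sigma_pos + sigma_neg not positive definite") from err

    # W^T total W = I and W^T sp W = diag(lambda+) in one symmetric-definite solve
    eigvals, W = scipy.linalg.eigh(sp, total)
    order = np.argsort(-eigvals, kind="stable")
    eigvals = eigvals[order]
    W = W[:, order]
    # deterministic sign: largest-magnitude entry of each filter positive
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    W = W * signs
    return SpatialFilterModel(W=W, eigvals_pos=np.clip(eigvals, 0.0, 1.0), class_order=class_order)


def csp_log_variance(
    trial: np.ndarray, model: SpatialFilterModel, n_pairs: int
) -> np.ndarray:
    """Log variance of the trial projected on ``2*n_pairs`` CSP filters.

    Takes the ``n_pairs`` filters with the largest positive-class
    eigenvalues and the ``n_pairs`` with the smallest (eigenvalue
    complementarity makes those the most negative-class-discriminative).
    """
    E = np.asarray(trial, dtype=float)
    n_ch = model.n_channels
    if E.ndim != 2 or E.shape[0] != n_ch:
        raise ValueError(f"trial has {E.shape[0]} channels, model expects {n_ch}")
    if n_pairs < 1 or 2 * n_pairs > n_ch:
        raise ValueError(f"need 1 <= n_pairs <= channels/2 = {n_ch // 2}")
    cols = np.r_[np.arange(n_pairs), np.arange(n_ch - n_pairs, n_ch)]
    projected = model.W[:, cols].T @ E
    var = projected.var(axis=1)
    if np.any(var <= 0):
        raise ValueError("constant projected signal: non-positive variance")
    return np.log(var)


@dataclass
class FBCSPModel:
    """Fitted filter bank + per-band CSP filters."""

    bank: FilterBankSpec
    per_band: list[SpatialFilterModel]
    n_pairs: int
    class_order: tuple
    fs: float = field(default=0.0)

    @property
    def n_features(self) -> int:
        return self.bank.n_bands * 2 * self.n_pairs


def fbcsp_fit(
    trials: TrialTensor,
    labels: np.ndarray | None = None,
    bank: FilterBankSpec | None = None,
    n_pairs: int = 2,
    positive_class=None,
) -> FBCSPModel:
    """Fit per-band CSP filters on labeled two-class trials.

    The positive class defaults to the later tag in sorted order (the same
    convention scikit-learn's binary classifiers use), so downstream score
    signs line up with the evidence projector.
    """
    labels = np.asarray(labels if labels is not None else trials.labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"FBCSP requires exactly 2 classes, got {list(classes)}")
    if bank is None:
        bank = default_eeg_bank()
    if positive_class is None:
        positive_class = classes[1]
    negative_class = classes[classes != positive_class][0]
    if 2 * n_pairs > trials.n_channels:
        raise ValueError("n_pairs too large for channel count")

    banded = apply_filter_bank(trials, bank)
    per_band = []
    for tensor in banded:
        sp = class_mean_covariance(tensor, labels, positive_class)
        sn = class_mean_covariance(tensor, labels, negative_class)
        per_band.append(fit_csp(sp, sn, class_order=(positive_class, negative_class)))
    return FBCSPModel(
        bank=bank,
        per_band=per_band,
        n_pairs=n_pairs,
        class_order=(positive_class, negative_class),
        fs=trials.fs,
    )


def band_scatter(trials: TrialTensor, bank: FilterBankSpec):
    """Per-band, per-trial scatter matrices for fast cross-validated refits.

    Filtering and the quadratic forms ``E E^T`` are label-independent, so a
    CV loop can compute them once and refit CSP per fold from cheap averages.
    Returns ``(scatter_raw, scatter_centered, n_samples)`` where both scatter
    stacks have shape ``(n_bands, n_trials, C, C)``; ``scatter_raw`` feeds the
    trace-normalized covariance and ``scatter_centered`` (mean-removed rows)
    reproduces ``np.var`` of projected signals exactly.
    """
    banded = apply_filter_bank(trials, bank)
    C = trials.n_channels
    raw = np.empty((bank.n_bands, trials.n_trials, C, C))
    centered = np.empty_like(raw)
    for b, tensor in enumerate(banded):
        for t in range(trials.n_trials):
            E = tensor.data[t]
            raw[b, t] = E @ E.T
            Ec = E - E.mean(axis=1, keepdims=True)
            centered[b, t] = Ec @ Ec.T
    return raw, centered, trials.n_samples


def fbcsp_fit_from_scatter(
    scatter_raw: np.ndarray,
    labels: np.ndarray,
    bank: FilterBankSpec,
    n_pairs: int,
    train_idx: np.ndarray,
    positive_class=None,
    fs: float = 0.0,
) -> FBCSPModel:
    """Fit FBCSP from precomputed scatter matrices on the ``train_idx`` trials."""
    labels = np.asarray(labels)
    classes = np.unique(labels[train_idx])
    if len(classes) != 2:
        raise ValueError("FBCSP requires exactly 2 classes in the training fold")
    if positive_class is None:
        positive_class = classes[1]
    negative_class = classes[classes != positive_class][0]
    per_band = []
    for b in range(bank.n_bands):
        covs = scatter_raw[b] / np.trace(scatter_raw[b], axis1=1, axis2=2)[:, None, None]
        sp = covs[train_idx][labels[train_idx] == positive_class].mean(axis=0)
        sn = covs[train_idx][labels[train_idx] == negative_class].mean(axis=0)
        per_band.append(fit_csp(sp, sn, class_order=(positive_class, negative_class)))
    return FBCSPModel(
        bank=bank, per_band=per_band, n_pairs=n_pairs,
        class_order=(positive_class, negative_class), fs=fs,
    )


def fbcsp_features_from_scatter(
    scatter_centered: np.ndarray, n_samples: int, model: FBCSPModel, n_pairs: int | None = None
) -> np.ndarray:
    """Band-major log-variance features from precomputed centered scatter."""
    n_pairs = model.n_pairs if n_pairs is None else n_pairs
    n_trials = scatter_centered.shape[1]
    width = 2 * n_pairs
    out = np.empty((n_trials, model.bank.n_bands * width))
    for b, sfm in enumerate(model.per_band):
        n_ch = sfm.n_channels
        cols = np.r_[np.arange(n_pairs), np.arange(n_ch - n_pairs, n_ch)]
        Ws = sfm.W[:, cols]
        var = np.einsum("ij,tjk,kl->til", Ws.T, scatter_centered[b], Ws).diagonal(
            axis1=1, axis2=2
        ) / n_samples
        if np.any(var <= 0):
            raise ValueError("constant projected signal: non-positive variance")
        out[:, b * width : (b + 1) * width] = np.log(var)
    return out


def fbcsp_transform(trials: TrialTensor, model: FBCSPModel) -> np.ndarray:
    """Concatenated band-major log-variance features, one row per trial."""
    if trials.n_channels != model.per_band[0].n_channels:
        raise ValueError(
            f"trial channel count {trials.n_channels} differs from fitted "
            f"model ({model.per_band[0].n_channels})"
        )
    banded = apply_filter_bank(trials, model.bank)
    features = np.empty((trials.n_trials, model.n_features))
    width = 2 * model.n_pairs
    for b, (tensor, sfm) in enumerate(zip(banded, model.per_band)):
        for t in range(trials.n_trials):
            features[t, b * width : (b + 1) * width] = csp_log_variance(
                tensor.data[t], sfm, model.n_pairs
            )
    return features
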