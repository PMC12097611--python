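"""Paired EEG / raw-Doppler trial simulator with known class structure.

Every downstream stage is validated against data whose ground truth is
known by construction.  Two paradigms are emulated:

* ``MI`` (motor imagery): two band-limited sources carrying mu (8-13 Hz)
  and beta (14-30 Hz) rhythm power whose variance is lateralized by class —
  imagining one arm suppresses the contralateral source's power.
* ``MRWG`` (flickering mental rotation / word generation): steady-state
  visually evoked components at 7 Hz (MR) and 17 Hz (WG) whose power is
  gated by class.

EEG trials are a noisy linear mixture of four sources (two informative,
two broadband background) through a full-column-rank mixing matrix.  Raw
Doppler trials are sums of randomly phased scatterer tones whose
instantaneous frequencies sit below the maximal Doppler shift implied by a
pulsatile velocity waveform

    v(t) = base_velocity * (1 + pulsatility * cardiac(t)) + class/side offset,

so the envelope stage can be checked against the exact v(t).  The cardiac
waveform is a raised-cosine systolic upstroke followed by an exponential
diastolic decay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import scipy.signal

from .containers import TrialTensor

__all__ = [
    "EEG_PARADIGM_CLASSES",
    "EEGSimConfig",
    "FTCDSimConfig",
    "PairedDataset",
    "generate_eeg_trials",
    "generate_ftcd_trials",
    "generate_paired_dataset",
    "cardiac_waveform",
    "true_velocity",
]

EEG_PARADIGM_CLASSES = {
    "MI": ("baseline", "left", "right"),
    "MRWG": ("baseline", "mr", "wg"),
}

#: power gain of each informative source per class (source 0, source 1)
_DEFAULT_GAINS = {
    "MI": {"baseline": (1.0, 1.0), "left": (1.0, 0.25), "right": (0.25, 1.0)},
    "MRWG": {"baseline": (0.0, 0.0), "mr": (1.0, 0.0), "wg": (0.0, 1.0)},
}

#: per-class (left, right) velocity offsets in cm/s; lateralized hemodynamics
_DEFAULT_OFFSETS = {
    "MI": {"baseline": (0.0, 0.0), "left": (0.0, 8.0), "right": (8.0, 0.0)},
    "MRWG": {"baseline": (0.0, 0.0), "mr": (0.0, 8.0), "wg": (8.0, 0.0)},
}

_SSVEP_FREQS = (7.0, 17.0)
_N_SOURCES = 4
_RAW_FTCD_FS = 44100.0
_FTCD_DECIMATION = 5
DEFAULT_FTCD_FS = _RAW_FTCD_FS / _FTCD_DECIMATION  # 8820 Hz after decimation


@dataclass
class EEGSimConfig:
    """Study-regime defaults: 16 channels, 256 Hz, 10 s trials."""

    n_trials_per_class: int = 50
    n_channels: int = 16
    fs: float = 256.0
    trial_len: float = 10.0
    paradigm: str = "MI"
    mixing_matrix: np.ndarray | None = None
    class_band_gains: dict | None = None
    snr_db: float = 10.0
    seed: int = 0
    classes: tuple | None = None

    def __post_init__(self) -> None:
        if self.paradigm not in EEG_PARADIGM_CLASSES:
            raise ValueError(f"unknown paradigm {self.paradigm!r}; use MI or MRWG")
        if self.classes is None:
            self.classes = EEG_PARADIGM_CLASSES[self.paradigm]
        if self.class_band_gains is None:
            self.class_band_gains = {
                c: _DEFAULT_GAINS[self.paradigm][c]
                for c in self.classes
                if c in _DEFAULT_GAINS[self.paradigm]
            }
        missing = [c for c in self.classes if c not in self.class_band_gains]
        if missing:
            raise ValueError(f"class_band_gains missing classes: {missing}")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        top = 30.0 if self.paradigm == "MI" else max(_SSVEP_FREQS)
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} too low for stimulated content up to {top} Hz"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_len))


def _resolve_mixing(cfg: EEGSimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.mixing_matrix is not None:
        A = np.asarray(cfg.mixing_matrix, dtype=float)
    else:
        A = rng.standard_normal((cfg.n_channels, _N_SOURCES)) / np.sqrt(_N_SOURCES)
    if A.shape[0] != cfg.n_channels:
        raise ValueError("mixing matrix row count must equal n_channels")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("singular mixing matrix (not full column rank)")
    return A


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    sos = scipy.signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = scipy.signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _informative_source(
    rng: np.random.Generator, cfg: EEGSimConfig, source_idx: int
) -> np.ndarray:
    n, fs = cfg.n_samples, cfg.fs
    if cfg.paradigm == "MI":
        # mu rhythm with a weaker beta component, unit power
        s = _band_noise(rng, n, fs, (8.0, 13.0)) + 0.6 * _band_noise(rng, n, fs, (14.0, 30.0))
        return s / s.std()
    f = _SSVEP_FREQS[source_idx]
    t = np.arange(n) / fs
    tone = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    nb = _band_noise(rng, n, fs, (max(f - 1.0, 0.5), f + 1.0))
    s = tone + 0.3 * nb
    return s / s.std()


def generate_eeg_trials(cfg: EEGSimConfig) -> TrialTensor:
    """Simulate labeled EEG trials, class-major, deterministic given the seed."""
    rng = np.random.default_rng(cfg.seed)
    A = _resolve_mixing(cfg, rng)
    n = cfg.n_samples
    trials, labels = [], []
    for cls in cfg.classes:
        g = np.sqrt(np.asarray(cfg.class_band_gains[cls], dtype=float))
        for _ in range(cfg.n_trials_per_class):
            S = np.empty((_N_SOURCES, n))
            S[0] = g[0] * _informative_source(rng, cfg, 0)
            S[1] = g[1] * _informative_source(rng, cfg, 1)
            S[2] = _band_noise(rng, n, cfg.fs, (2.0, min(60.0, cfg.fs / 2 - 1)))
            S[3] = _band_noise(rng, n, cfg.fs, (2.0, min(60.0, cfg.fs / 2 - 1)))
            clean = A @ S
            noise_sd = np.sqrt(clean.var() * 10 ** (-cfg.snr_db / 10))
            trials.append(clean + noise_sd * rng.standard_normal(clean.shape))
            labels.append(cls)
    return TrialTensor(
        data=np.stack(trials),
        fs=cfg.fs,
        labels=np.asarray(labels),
        channel_names=[f"ch{i:02d}" for i in range(cfg.n_channels)],
    )


@dataclass
class FTCDSimConfig:
    """Study-regime defaults: 8820 Hz (44.1 kHz decimated by 5), 10 s trials."""

    n_trials_per_class: int = 50
    fs: float = DEFAULT_FTCD_FS
    trial_len: float = 10.0
    heart_rate: float = 1.2  # Hz
    base_velocity: float = 60.0  # cm/s, mid-range MCA flow
    class_velocity_offsets: dict | None = None
    carrier_ft: float = 2.0e6  # transmitted ultrasound frequency, Hz
    c_sound: float = 1540.0  # m/s
    noise_floor_db: float = -20.0  # noise power relative to echo power
    pulsatility: float = 0.4
    n_scatterers: int = 25
    velocity_jitter: float = 3.0  # per-trial, per-side sd of baseline CBFV, cm/s
    paradigm: str = "MI"
    seed: int = 0
    classes: tuple | None = None

    def __post_init__(self) -> None:
        if self.base_velocity <= 0:
            raise ValueError("base_velocity must be positive")
        if not 0.5 < self.heart_rate < 3.0:
            raise ValueError("heart_rate must lie in (0.5, 3) Hz")
        if self.classes is None:
            self.classes = EEG_PARADIGM_CLASSES[self.paradigm]
        if self.class_velocity_offsets is None:
            self.class_velocity_offsets = {
                c: _DEFAULT_OFFSETS[self.paradigm][c]
                for c in self.classes
                if c in _DEFAULT_OFFSETS[self.paradigm]
            }
        missing = [c for c in self.classes if c not in self.class_velocity_offsets]
        if missing:
            raise ValueError(f"class_velocity_offsets missing classes: {missing}")
        v_max = (
            self.base_velocity * (1 + self.pulsatility)
            + max(max(off) for off in self.class_velocity_offsets.values())
            + 4 * self.velocity_jitter
        )
        f_max = 2 * self.carrier_ft * (v_max / 100.0) / self.c_sound
        if f_max >= self.fs / 2:
            raise ValueError(
                f"maximal Doppler shift {f_max:.0f} Hz reaches Nyquist ({self.fs / 2:.0f} Hz)"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_len))


def cardiac_waveform(t: np.ndarray, heart_rate: float, phase: float = 0.0) -> np.ndarray:
    """Normalized cardiac cycle in [0, 1]: raised-cosine systole, exponential diastole.

    ``phase`` shifts the cycle (in fractions of a beat).  Systolic upstroke
    occupies 15% of the cycle; the diastolic decay constant is 25% of it.
    """
    frac = (np.asarray(t, dtype=float) * heart_rate + phase) % 1.0
    tp, tau = 0.15, 0.25
    rise = 0.5 * (1 - np.cos(np.pi * frac / tp))
    decay = np.exp(-(frac - tp) / tau)
    return np.where(frac < tp, rise, decay)


def true_velocity(
    truth: dict, trial: int, side: int, t: np.ndarray
) -> np.ndarray:
    """Reconstruct the generating v(t) (cm/s) for one trial and side."""
    return truth["base_velocity"] * (
        1.0
        + truth["pulsatility"]
        * cardiac_waveform(t, truth["heart_rate"], truth["phase"][trial])
    ) + truth["offsets"][trial, side]


def _doppler_shift_hz(v_cm_s: np.ndarray, f_t: float, c: float) -> np.ndarray:
    return 2.0 * f_t * (v_cm_s / 100.0) / c


def generate_ftcd_trials(
    cfg: FTCDSimConfig, return_truth: bool = False
) -> TrialTensor | tuple[TrialTensor, dict]:
    """Simulate 2-channel raw Doppler trials.

    Each channel is a sum of ``n_scatterers`` randomly phased tones whose
    instantaneous frequencies are fixed fractions of the maximal Doppler
    shift implied by v(t); the fastest scatterer sits exactly at the edge
    with unit amplitude, so the spectral edge marks v(t).  White noise is
    added at ``noise_floor_db`` relative to the echo power (``-inf`` for a
    noiseless trial).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    n_trials_total = len(cfg.classes) * cfg.n_trials_per_class
    data = np.empty((n_trials_total, 2, n))
    labels, phases, offsets = [], [], []
    k = 0
    for cls in cfg.classes:
        class_off = cfg.class_velocity_offsets[cls]
        for _ in range(cfg.n_trials_per_class):
            phase = rng.uniform(0, 1)
            card = cardiac_waveform(t, cfg.heart_rate, phase)
            # physiological trial-to-trial variability of baseline flow
            off = tuple(
                class_off[s] + cfg.velocity_jitter * rng.standard_normal()
                for s in range(2)
            )
            for side in range(2):
                v = cfg.base_velocity * (1 + cfg.pulsatility * card) + off[side]
                f_edge = _doppler_shift_hz(v, cfg.carrier_ft, cfg.c_sound)
                F = np.cumsum(f_edge) / cfg.fs  # integrated edge frequency, cycles
                # stratified velocity fractions: consecutive scatterers stay
                # spectrally resolvable, so no pair beats slowly enough to
                # blank the edge for whole analysis windows
                n_sc = cfg.n_scatterers
                u = 1.0 - (np.arange(n_sc) + rng.uniform(0.25, 0.75, n_sc)) / n_sc
                a = rng.uniform(0.5, 1.0, n_sc)
                u[0], a[0] = 1.0, 1.0  # fastest scatterer pins the spectral edge
                theta = rng.uniform(0, 2 * np.pi, cfg.n_scatterers)
                sig = (a[:, None] * np.cos(2 * np.pi * u[:, None] * F + theta[:, None])).sum(axis=0)
                if np.isfinite(cfg.noise_floor_db):
                    noise_sd = np.sqrt(sig.var() * 10 ** (cfg.noise_floor_db / 10))
                    sig = sig + noise_sd * rng.standard_normal(n)
                data[k, side] = sig
            labels.append(cls)
            phases.append(phase)
            offsets.append(off)
            k += 1
    tensor = TrialTensor(
        data=data, fs=cfg.fs, labels=np.asarray(labels), channel_names=["left", "right"]
    )
    if not return_truth:
        return tensor
    truth = {
        "phase": np.asarray(phases),
        "offsets": np.asarray(offsets, dtype=float),
        "heart_rate": cfg.heart_rate,
        "base_velocity": cfg.base_velocity,
        "pulsatility": cfg.pulsatility,
        "labels": np.asarray(labels),
    }
    return tensor, truth


@dataclass
class PairedDataset:
    """Aligned EEG and raw-Doppler trials for one binary problem."""

    eeg: TrialTensor
    ftcd_raw: TrialTensor
    labels: np.ndarray
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.eeg.n_trials != self.ftcd_raw.n_trials:
            raise ValueError("EEG and fTCD trial counts differ")
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.eeg.n_trials:
            raise ValueError("label count does not match trial count")
        if len(np.unique(self.labels)) != 2:
            raise ValueError("paired dataset must contain exactly 2 classes")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.eeg.save(outdir / "eeg")
        self.ftcd_raw.save(outdir / "ftcd")
        arrays = {
            k: v for k, v in self.truth.items() if isinstance(v, np.ndarray)
        }
        scalars = {k: v for k, v in self.truth.items() if not isinstance(v, np.ndarray)}
        np.savez(outdir / "truth.npz", **arrays)
        (outdir / "truth.json").write_text(json.dumps(scalars, indent=2, default=str))

    @classmethod
    def load(cls, outdir: str | Path) -> "PairedDataset":
        outdir = Path(outdir)
        eeg = TrialTensor.load(outdir / "eeg")
        ftcd = TrialTensor.load(outdir / "ftcd")
        truth: dict = {}
        tf = outdir / "truth.json"
        if tf.exists():
            truth.update(json.loads(tf.read_text()))
        tn = outdir / "truth.npz"
        if tn.exists():
            with np.load(tn, allow_pickle=False) as f:
                truth.update({k: f[k] for k in f.files})
        return cls(eeg=eeg, ftcd_raw=ftcd, labels=eeg.labels, truth=truth)


def _parse_problem(problem, available: tuple) -> tuple:
    if isinstance(problem, str):
        parts = problem.replace("_vs_", "-vs-").split("-vs-")
        if len(parts) != 2:
            raise ValueError(f"cannot parse problem {problem!r}; use 'a-vs-b'")
        problem = tuple(parts)
    pair = tuple(problem)
    if len(pair) != 2 or len(set(pair)) != 2:
        raise ValueError("problem must name two distinct classes")
    for c in pair:
        if c not in available:
            raise ValueError(f"class {c!r} not in paradigm classes {available}")
    return pair


def generate_paired_dataset(
    eeg_cfg: EEGSimConfig, ftcd_cfg: FTCDSimConfig, problem
) -> PairedDataset:
    """Generate aligned EEG + fTCD trials restricted to a binary problem."""
    if eeg_cfg.n_trials_per_class != ftcd_cfg.n_trials_per_class:
        raise ValueError("EEG and fTCD configs must share n_trials_per_class")
    pair = _parse_problem(problem, eeg_cfg.classes)
    eeg_cfg = replace(eeg_cfg, classes=pair)
    ftcd_cfg = replace(ftcd_cfg, classes=pair)
    eeg = generate_eeg_trials(eeg_cfg)
    ftcd, truth = generate_ftcd_trials(ftcd_cfg, return_truth=True)
    assert np.array_equal(eeg.labels, ftcd.labels)
    full_truth = {
        "problem": "-vs-".join(pair),
        "eeg_snr_db": eeg_cfg.snr_db,
        "eeg_class_band_gains": {c: list(eeg_cfg.class_band_gains[c]) for c in pair},
        "ftcd_class_velocity_offsets": {
            c: list(ftcd_cfg.class_velocity_offsets[c]) for c in pair
        },
        "seed_eeg": eeg_cfg.seed,
        "seed_ftcd": ftcd_cfg.seed,
        **truth,
    }
    return PairedDataset(eeg=eeg, ftcd_raw=ftcd, labels=eeg.labels, truth=full_truth)
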