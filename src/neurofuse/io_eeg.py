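"""EEG import helpers: EDF recordings and delimited-text sample matrices.

Real recordings enter the pipeline as a continuous multichannel signal
that is epoched into fixed-length trials; labels ride in a sidecar
delimited file (one label per trial).  Acquisition-style filtering
(band-pass plus mains notch) is optional and off for synthetic data,
which is generated inside the analysis band already.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

from .containers import TrialTensor

__all__ = [
    "epoch_continuous",
    "eeg_trials_from_delimited",
    "eeg_trials_from_edf",
    "acquisition_filter",
]


def epoch_continuous(
    data: np.ndarray, fs: float, trial_len: float,
    labels: np.ndarray | None = None, channel_names: list[str] | None = None,
) -> TrialTensor:
    """Cut a (channels, samples) continuous signal into back-to-back trials."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_per = int(round(trial_len * fs))
    n_trials = data.shape[1] // n_per
    if n_trials < 1:
        raise ValueError("recording shorter than one trial")
    trials = data[:, : n_trials * n_per].reshape(data.shape[0], n_trials, n_per)
    trials = np.transpose(trials, (1, 0, 2))
    if labels is not None:
        labels = np.asarray(labels)[:n_trials]
    return TrialTensor(trials, fs=fs, labels=labels, channel_names=channel_names)


def eeg_trials_from_delimited(
    path: str | Path, fs: float, trial_len: float,
    labels_path: str | Path | None = None,
) -> TrialTensor:
    """Read a delimited text file (samples x channels, header row) and epoch it."""
    frame = pd.read_csv(path)
    labels = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path)["label"].to_numpy()
    return epoch_continuous(
        frame.to_numpy().T, fs=fs, trial_len=trial_len, labels=labels,
        channel_names=list(frame.columns),
    )


def eeg_trials_from_edf(
    path: str | Path, trial_len: float, labels_path: str | Path | None = None,
) -> TrialTensor:
    """Read an EDF recording (via MNE) and epoch it into fixed-length trials."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("EDF import requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path)["label"].to_numpy()
    return epoch_continuous(
        raw.get_data(), fs=float(raw.info["sfreq"]), trial_len=trial_len,
        labels=labels, channel_names=list(raw.ch_names),
    )


def acquisition_filter(
    trials: TrialTensor,
    band: tuple[float, float] = (2.0, 62.0),
    notch: tuple[float, float] | None = (58.0, 62.0),
    order: int = 4,
) -> TrialTensor:
    """Acquisition-style band-pass plus mains-notch filtering.

    Mirrors amplifier-side preprocessing of real recordings; synthetic
    trials are generated in-band and skip this.  Zero-phase throughout.
    """
    hi = min(band[1], trials.fs / 2 - 1e-6)
    sos = scipy.signal.butter(order, [band[0], hi], btype="bandpass",
                              fs=trials.fs, output="sos")
    data = scipy.signal.sosfiltfilt(sos, trials.data, axis=-1)
    if notch is not None and notch[0] < trials.fs / 2:
        n_hi = min(notch[1], trials.fs / 2 - 1e-6)
        sos_n = scipy.signal.butter(order, [notch[0], n_hi], btype="bandstop",
                                    fs=trials.fs, output="sos")
        data = scipy.signal.sosfiltfilt(sos_n, data, axis=-1)
    return TrialTensor(data, fs=trials.fs, labels=trials.labels,
                       channel_names=trials.channel_names)
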