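"""Labeled multichannel trial containers shared by every pipeline stage.

A :class:`TrialTensor` is the in-memory unit of exchange between the
simulator, the EEG spatial-filtering stage and the Doppler envelope stage:
a ``(trials, channels, samples)`` array plus its sampling rate and optional
per-trial class labels.  On disk a trial set is an ``.npz`` array container
with a delimited-text label sidecar, so datasets stay plain and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrialTensor"]


@dataclass
class TrialTensor:
    """Set of labeled multichannel trials for one modality.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Real-valued trial matrix stack.  Must be finite.
    fs : float
        Sampling rate in Hz.
    labels : ndarray of str, optional
        Per-trial class tag, aligned with the first axis of ``data``.
    channel_names : list of str, optional
        One name per channel.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray | None = None
    channel_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"trial data must be (trials, channels, samples); got shape {self.data.shape}"
            )
        if self.data.shape[1] < 2:
            raise ValueError("at least 2 channels required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.data.shape[0]:
                raise ValueError(
                    f"{len(self.labels)} labels for {self.data.shape[0]} trials"
                )
        if self.channel_names is not None and len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length does not match channel count")

    # -- shape accessors ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs

    def select(self, index: np.ndarray) -> "TrialTensor":
        """Return a new tensor restricted to the trials in ``index``."""
        index = np.asarray(index)
        return TrialTensor(
            data=self.data[index],
            fs=self.fs,
            labels=None if self.labels is None else self.labels[index],
            channel_names=self.channel_names,
        )

    def classes(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("tensor has no labels")
        return np.unique(self.labels)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write arrays to ``<path>.npz`` and labels to ``<path>.labels.csv``."""
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            data=self.data,
            fs=np.asarray(self.fs),
            channel_names=np.asarray(self.channel_names or [], dtype=str),
        )
        if self.labels is not None:
            pd.DataFrame({"trial": np.arange(self.n_trials), "label": self.labels}).to_csv(
                path.with_suffix(".labels.csv"), index=False
            )

    @classmethod
    def load(cls, path: str | Path) -> "TrialTensor":
        path = Path(path)
        npz = path.with_suffix(".npz")
        if not npz.exists():
            raise FileNotFoundError(f"missing array container: {npz}")
        with np.load(npz) as f:
            data = f["data"]
            fs = float(f["fs"])
            names = [str(c) for c in f["channel_names"]] or None
        labels = None
        label_file = path.with_suffix(".labels.csv")
        if label_file.exists():
            labels = pd.read_csv(label_file)["label"].to_numpy()
        return cls(data=data, fs=fs, labels=labels, channel_names=names)
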