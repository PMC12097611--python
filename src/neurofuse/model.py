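"""Model/Results front door for the multimodal fusion pipeline.

``MultimodalFusion`` is built from a :class:`~neurofuse.synthetic.PairedDataset`
(or loaded from files) and its :meth:`fit` runs the cross-validated
pipeline, returning a :class:`FusionCVResults` that carries the accuracy
estimates, the selected hyper-parameters and a printable summary table.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fusion import CVConfig, CVReport, run_cross_validation
from .synthetic import PairedDataset

__all__ = ["MultimodalFusion", "FusionCVResults"]


class MultimodalFusion:
    """Weighted Bayesian EEG + fTCD fusion evaluated by cross-validation.

    Parameters
    ----------
    dataset : PairedDataset
        Aligned two-class EEG and raw-Doppler trials.
    config : CVConfig, optional
        Evaluation settings; defaults to the leakage-free nested protocol
        with 10 stratified folds.
    """

    def __init__(self, dataset: PairedDataset, config: CVConfig | None = None):
        self.dataset = dataset
        self.config = config or CVConfig()

    @classmethod
    def from_files(cls, directory: str | Path, config: CVConfig | None = None):
        """Build the model from a saved dataset directory."""
        return cls(PairedDataset.load(directory), config=config)

    def fit(self, **overrides) -> "FusionCVResults":
        """Run the cross-validated evaluation; overrides patch the config."""
        cfg = replace(self.config, **overrides) if overrides else self.config
        report = run_cross_validation(self.dataset, cfg)
        return FusionCVResults(self, report)


class FusionCVResults:
    """Results wrapper: accuracies, hyper-parameters, summary and plots."""

    def __init__(self, model: MultimodalFusion, report: CVReport):
        self.model = model
        self.report = report

    # convenience accessors -------------------------------------------------
    @property
    def mean_accuracy(self) -> float:
        return self.report.mean_accuracy

    @property
    def best_alpha(self) -> float:
        return self.report.best_alpha

    def to_frame(self) -> pd.DataFrame:
        r = self.report
        return pd.DataFrame(
            {
                "metric": [
                    "fused accuracy (%)",
                    "EEG-only accuracy (%)",
                    "fTCD-only accuracy (%)",
                    "EEG SVM accuracy (%)",
                    "fTCD SVM accuracy (%)",
                    "best alpha",
                    "best n_pairs",
                ],
                "value": [
                    r.mean_accuracy,
                    r.eeg_accuracy,
                    r.ftcd_accuracy,
                    r.eeg_svm_accuracy,
                    r.ftcd_svm_accuracy,
                    r.best_alpha,
                    r.best_n_pairs,
                ],
            }
        )

    def summary(self) -> str:
        r = self.report
        problem = self.model.dataset.truth.get("problem", "-vs-".join(
            map(str, self.model.dataset.classes)))
        lines = [
            "Multimodal EEG-fTCD fusion: cross-validated results",
            "=" * 53,
            f"problem:            {problem}",
            f"trials:             {self.model.dataset.eeg.n_trials}",
            f"folds:              {r.n_folds}  (mode: {r.mode}, seed {r.seed})",
            f"fused accuracy:     {r.mean_accuracy:6.2f} % +/- {r.std_accuracy:.2f}",
            f"EEG-only accuracy:  {r.eeg_accuracy:6.2f} %",
            f"fTCD-only accuracy: {r.ftcd_accuracy:6.2f} %",
            f"best alpha:         {r.best_alpha:.2f}   (EEG weight)",
            f"best n_pairs:       {r.best_n_pairs}",
        ]
        if r.fallback_folds:
            lines.append(
                f"note: rank-sum screening fell back to the single best "
                f"feature in {r.fallback_folds} fold(s)"
            )
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Structured JSON summary of the report."""
        Path(path).write_text(json.dumps(self.report.to_dict(), indent=2))

    def plot_alpha_curve(self, ax=None):
        """Accuracy versus alpha (paper mode only, where the curve exists)."""
        if self.report.alpha_curve is None:
            raise ValueError("no alpha curve available (run with mode='paper')")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(0, 1, len(self.report.alpha_curve))
        ax.plot(grid, self.report.alpha_curve)
        ax.axvline(self.report.best_alpha, ls="--", color="k", lw=0.8)
        ax.set_xlabel("alpha (EEG weight)")
        ax.set_ylabel("mean CV accuracy (%)")
        return ax
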