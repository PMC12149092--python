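"""Model/Results front end over the full pipeline.

:class:`VisibilityGraphModel` bundles the feature-extraction choices
(reference scheme, window length, bands, Welch configuration, feature mode)
with a classifier architecture; :meth:`~VisibilityGraphModel.fit` runs the
repeated stratified cross-validation protocol and returns a
:class:`CVResults` carrying per-fold metrics, their means and standard
deviations, the mean ROC curve, and a ``summary()`` table.

Example
-------
>>> from vgeeg.synthetic import alpha_contrast_spec, generate_cohort
>>> from vgeeg.classifier import VisibilityGraphModel
>>> cohort = generate_cohort(alpha_contrast_spec(n_subjects_per_class=5))
>>> model = VisibilityGraphModel.from_recordings(cohort, window_length=5.0)
>>> res = model.fit(folds=5, repeats=3, seed=0)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .eeg_io import Recording, apply_reference, segment_windows
from .evaluation import EvalReport, repeated_cv
from .features import FeatureRow, assemble
from .models import ModelSpec, TrainingParams
from .spectral import BandDefinition, DEFAULT_BANDS, WelchParams

__all__ = ["VisibilityGraphModel", "CVResults"]


class VisibilityGraphModel:
    """EEG window classifier on visibility-graph and band-power features."""

    def __init__(
        self,
        rows: Sequence[FeatureRow],
        model_spec: ModelSpec | None = None,
    ):
        if not rows:
            raise ValueError("no feature rows")
        self.rows = list(rows)
        self.model_spec = model_spec or ModelSpec()

    @classmethod
    def from_recordings(
        cls,
        recordings: Sequence[Recording],
        window_length: float,
        mode: str = "combined",
        reference: str = "common_average",
        bands: Sequence[BandDefinition] = DEFAULT_BANDS,
        welch: WelchParams | None = None,
        model_spec: ModelSpec | None = None,
    ) -> "VisibilityGraphModel":
        """Reference, window and featurize recordings, then wrap the rows."""
        windows = []
        for rec in recordings:
            windows.extend(segment_windows(apply_reference(rec, reference), window_length))
        rows = assemble(windows, mode=mode, bands=bands, welch=welch)
        return cls(rows, model_spec)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        mode: str = "combined",
        model_spec: ModelSpec | None = None,
    ) -> "VisibilityGraphModel":
        from .features import frame_to_rows

        return cls(frame_to_rows(df, mode), model_spec)

    def fit(
        self,
        folds: int = 5,
        repeats: int = 10,
        grouping: str = "by_window",
        seed: int = 0,
    ) -> "CVResults":
        report = repeated_cv(
            self.rows, self.model_spec, folds, repeats, grouping, seed
        )
        return CVResults(self, report)


@dataclass
class CVResults:
    """Cross-validated performance estimates with their uncertainties."""

    model: VisibilityGraphModel
    report: EvalReport

    @property
    def per_fold(self) -> pd.DataFrame:
        return self.report.per_fold_frame()

    @property
    def metrics(self) -> dict:
        return self.report.aggregate

    @property
    def mean_auc(self) -> float:
        return self.report.mean_auc

    def summary(self) -> str:
        rep = self.report
        spec = self.model.model_spec
        mode = self.model.rows[0].mode
        lines = [
            "        Visibility-graph EEG classification — repeated CV",
            "=" * 66,
            f"architecture: {spec.architecture:<16} feature mode: {mode}",
            f"folds: {rep.folds}   repeats: {rep.repeats}   grouping: {rep.grouping}"
            f"   seed: {rep.seed}",
            f"windows: {len(self.model.rows)}   features: "
            f"{len(self.model.rows[0].layout)}",
            "-" * 66,
            f"{'metric':<12}{'mean':>10}{'std':>10}",
        ]
        for m in ("accuracy", "precision", "recall", "f1", "auc"):
            agg = rep.aggregate[m]
            lines.append(f"{m:<12}{agg['mean']:>10.3f}{agg['std']:>10.3f}")
        lines.append("=" * 66)
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Mean ROC curve (vertical averaging over the FPR grid)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.plot(
            self.report.roc_fpr,
            self.report.roc_mean_tpr,
            label=f"mean ROC (AUC = {self.report.mean_auc:.3f})",
        )
        ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8, label="chance")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        return ax
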