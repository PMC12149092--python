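"""Repeated stratified cross-validation, classification metrics and mean ROC.

The protocol is k-fold stratified cross-validation repeated several times
with fresh shuffles; the reported metrics (accuracy, precision, recall, F1)
are averaged over all folds of all repeats, and the ROC curve is averaged
vertically over a fixed 101-point false-positive-rate grid.

Fold grouping is a required analysis choice: ``by_window`` splits at the
window level (windows of one subject can land in both train and test, which
leaks subject identity and inflates scores on clinical EEG — a warning is
logged), ``by_subject`` keeps every subject's windows on one side of the
split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .features import FeatureRow, standardize
from .models import FittedModel, ModelSpec, fit, predict_proba

logger = logging.getLogger(__name__)

__all__ = ["ConfusionCounts", "classification_metrics", "roc_points",
           "EvalReport", "repeated_cv"]

FPR_GRID = np.linspace(0.0, 1.0, 101)
METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, labels: Sequence[int], predictions: Sequence[int]
    ) -> "ConfusionCounts":
        y = np.asarray(labels, dtype=int)
        p = np.asarray(predictions, dtype=int)
        return cls(
            tp=int(((y == 1) & (p == 1)).sum()),
            fp=int(((y == 0) & (p == 1)).sum()),
            tn=int(((y == 0) & (p == 0)).sum()),
            fn=int(((y == 1) & (p == 0)).sum()),
        )


def classification_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1); zero-division cases return 0."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        logger.warning("no positive predictions; precision set to 0")
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        logger.warning("no positive labels; recall set to 0")
        recall = 0.0
    else:
        recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f1


def roc_points(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep over the scores, and its trapezoidal AUC."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class EvalReport:
    """Per-fold and aggregated results of one repeated-CV run."""

    per_fold: list[dict]  # repeat, fold, accuracy, precision, recall, f1, auc
    aggregate: dict  # metric -> {"mean": ..., "std": ...}
    roc_fpr: np.ndarray
    roc_mean_tpr: np.ndarray
    mean_auc: float
    folds: int
    repeats: int
    grouping: str
    seed: int

    def per_fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_fold)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": m, **self.aggregate[m]} for m in (*METRIC_NAMES, "auc")
        ]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "per_fold": self.per_fold,
            "aggregate": self.aggregate,
            "roc": {
                "fpr": self.roc_fpr.tolist(),
                "mean_tpr": self.roc_mean_tpr.tolist(),
                "mean_auc": self.mean_auc,
            },
            "folds": self.folds,
            "repeats": self.repeats,
            "grouping": self.grouping,
            "seed": self.seed,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def _fold_indices(
    labels: np.ndarray,
    groups: np.ndarray,
    folds: int,
    grouping: str,
    seed: int,
):
    if grouping == "by_window":
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return splitter.split(np.zeros(len(labels)), labels)
    if grouping == "by_subject":
        splitter = StratifiedGroupKFold(
            n_splits=folds, shuffle=True, random_state=seed
        )
        return splitter.split(np.zeros(len(labels)), labels, groups)
    raise ValueError(f"unknown grouping {grouping!r}")


def repeated_cv(
    rows: Sequence[FeatureRow],
    spec: ModelSpec,
    folds: int = 5,
    repeats: int = 10,
    grouping: str = "by_window",
    seed: int = 0,
) -> EvalReport:
    """Run ``repeats`` independent rounds of stratified ``folds``-fold CV.

    Per fold: z-scoring fitted on the training split only, model fitted
    with a fold-specific derived seed, held-out windows scored at the 0.5
    threshold for the confusion metrics and threshold-free for ROC/AUC.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rows = list(rows)
    labels = np.array([r.label for r in rows], dtype=int)
    groups = np.array([r.subject_id for r in rows])
    if grouping == "by_window" and len(set(groups.tolist())) > 1:
        logger.warning(
            "by_window grouping: windows of one subject may appear in both "
            "train and test folds (subject-identity leakage); consider "
            "grouping='by_subject'"
        )
    per_fold: list[dict] = []
    tprs: list[np.ndarray] = []
    aucs: list[float] = []
    for rep in range(repeats):
        rep_seed = int(
            np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31 - 1)
        )
        for fold_i, (tr_idx, te_idx) in enumerate(
            _fold_indices(labels, groups, folds, grouping, rep_seed)
        ):
            train = [rows[i] for i in tr_idx]
            test = [rows[i] for i in te_idx]
            train_s, test_s = standardize(train, test)
            fold_spec = ModelSpec(
                architecture=spec.architecture,
                training=type(spec.training)(
                    epochs=spec.training.epochs,
                    batch_size=spec.training.batch_size,
                    learning_rate=spec.training.learning_rate,
                    seed=int(
                        np.random.SeedSequence(
                            [spec.training.seed, rep, fold_i]
                        ).generate_state(1)[0]
                        % (2**31 - 1)
                    ),
                ),
            )
            fitted = fit(fold_spec, train_s)
            probs = predict_proba(fitted, test_s)
            y_te = labels[te_idx]
            counts = ConfusionCounts.from_predictions(y_te, (probs >= 0.5).astype(int))
            acc, prec, rec, f1 = classification_metrics(counts)
            entry = {
                "repeat": rep,
                "fold": fold_i,
                "accuracy": acc,
                "precision": prec,
                "recall": rec,
                "f1": f1,
            }
            if len(set(y_te.tolist())) == 2:
                fpr, tpr, auc = roc_points(y_te, probs)
                tprs.append(np.interp(FPR_GRID, fpr, tpr))
                aucs.append(auc)
                entry["auc"] = auc
            per_fold.append(entry)
    aggregate = {}
    for m in METRIC_NAMES:
        vals = np.array([e[m] for e in per_fold])
        aggregate[m] = {"mean": float(vals.mean()), "std": float(vals.std())}
    auc_arr = np.array(aucs) if aucs else np.array([np.nan])
    aggregate["auc"] = {"mean": float(auc_arr.mean()), "std": float(auc_arr.std())}
    mean_tpr = (
        np.mean(np.stack(tprs), axis=0) if tprs else np.full_like(FPR_GRID, np.nan)
    )
    if len(mean_tpr) and not np.isnan(mean_tpr[0]):
        mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return EvalReport(
        per_fold=per_fold,
        aggregate=aggregate,
        roc_fpr=FPR_GRID.copy(),
        roc_mean_tpr=mean_tpr,
        mean_auc=float(auc_arr.mean()),
        folds=folds,
        repeats=repeats,
        grouping=grouping,
        seed=seed,
    )
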