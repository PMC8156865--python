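"""Evaluation harness: classification metrics, coverage-aware accuracy, CV.

Abstention makes plain accuracy unfair to compare against a full-coverage
ensemble, so two coverage-aware metrics are used:

* Weighted Average Accuracy (WAA): fold accuracies on the *included*
  (non-abstained) images, weighted by the included counts ``d_i``:
  ``WAA = sum_i(Accuracy_i * d_i) / sum_i d_i``.
* Abstain Percentage (AP): excluded images as a percentage of the dataset,
  ``AP = 100 * sum_i R_i / DS``.

When nothing is excluded WAA degenerates to pooled accuracy and AP to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import KFold, StratifiedKFold

from .elastic import ABSTAIN, MemberPrediction, grade_predictions

__all__ = [
    "FoldOutcome",
    "EvalReport",
    "classification_metrics",
    "waa",
    "ap",
    "fold_outcomes",
    "beta_sweep",
    "crossval_split",
]


@dataclass(frozen=True)
class FoldOutcome:
    """Per-fold bookkeeping: included count d_i, excluded count R_i, hits."""

    fold_id: int
    n_included: int
    n_excluded: int
    n_correct_included: int

    def __post_init__(self) -> None:
        if min(self.n_included, self.n_excluded, self.n_correct_included) < 0:
            raise ValueError("fold counts must be non-negative")
        if self.n_correct_included > self.n_included:
            raise ValueError("cannot have more correct than included images")

    @property
    def accuracy_included(self) -> float | None:
        """Accuracy on included images; None when the fold is fully excluded."""
        if self.n_included == 0:
            return None
        return self.n_correct_included / self.n_included


@dataclass(frozen=True)
class EvalReport:
    """Aggregate evaluation over all folds at one beta."""

    confusion: np.ndarray
    per_class: pd.DataFrame  # rows: one per grade plus "Total" macro row
    accuracy: float | None
    waa: float | None
    ap: float
    dataset_size: int
    beta: float


def classification_metrics(
    truths: Sequence[int],
    predictions: Sequence[int],
    c: int,
    average: str = "macro",
) -> tuple[np.ndarray, pd.DataFrame, float]:
    """Confusion matrix and per-class one-vs-rest metrics.

    Abstained images must already be removed by the caller.  Per class:
    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R), accuracy =
    (TP+TN)/n one-vs-rest.  The "Total" row is the unweighted macro average
    by default (``average="weighted"`` weights by class support).  Zero
    divisions yield 0 with a warning.
    """
    truths = np.asarray(truths, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if truths.shape != predictions.shape:
        raise ValueError("truths and predictions must have equal length")
    cm = confusion_matrix(truths, predictions, labels=np.arange(c))

    n = cm.sum()
    rows = []
    for k in range(c):
        tp = cm[k, k]
        fp = cm[:, k].sum() - tp
        fn = cm[k, :].sum() - tp
        tn = n - tp - fp - fn
        prec = _safe_div(tp, tp + fp, f"class {k} precision")
        rec = _safe_div(tp, tp + fn, f"class {k} recall")
        f1 = _safe_div(2 * prec * rec, prec + rec, f"class {k} F1")
        acc = _safe_div(tp + tn, n, f"class {k} accuracy")
        rows.append({"grade": k, "precision": prec, "recall": rec,
                     "f1": f1, "accuracy": acc, "support": cm[k, :].sum()})
    table = pd.DataFrame(rows)

    if average == "weighted":
        w = table["support"].to_numpy(dtype=float)
        w = w / w.sum() if w.sum() else np.full(c, 1.0 / c)
    elif average == "macro":
        w = np.full(c, 1.0 / c)
    else:
        raise ValueError(f"average must be 'macro' or 'weighted', got {average!r}")
    total = {
        "grade": "Total",
        **{m: float(np.dot(w, table[m])) for m in ("precision", "recall", "f1", "accuracy")},
        "support": int(n),
    }
    table = pd.concat([table, pd.DataFrame([total])], ignore_index=True)
    overall_accuracy = _safe_div(np.trace(cm), n, "overall accuracy")
    return cm, table, overall_accuracy


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero division, reporting 0", stacklevel=3)
        return 0.0
    return float(num / den)


def waa(folds: Sequence[FoldOutcome]) -> float:
    """Weighted Average Accuracy over folds: sum(Acc_i * d_i) / sum(d_i)."""
    d = np.array([f.n_included for f in folds])
    if d.sum() == 0:
        raise ValueError("WAA undefined: every fold excluded all images")
    hits = np.array([f.n_correct_included for f in folds])
    return float(hits.sum() / d.sum())


def ap(folds: Sequence[FoldOutcome], dataset_size: int) -> float:
    """Abstain Percentage: 100 * sum(R_i) / DS."""
    if dataset_size <= 0:
        raise ValueError("dataset_size must be positive")
    total = sum(f.n_included + f.n_excluded for f in folds)
    if total != dataset_size:
        raise ValueError(
            f"fold counts sum to {total}, expected dataset_size={dataset_size}"
        )
    return 100.0 * sum(f.n_excluded for f in folds) / dataset_size


def fold_outcomes(
    grades: Mapping[str, int],
    truths: Mapping[str, int],
    fold_of_image: Mapping[str, int],
) -> list[FoldOutcome]:
    """Tally per-fold included/excluded/correct counts from per-image grades.

    ``grades`` maps image_id to the predicted grade or :data:`ABSTAIN`.
    """
    fold_ids = sorted(set(fold_of_image.values()))
    out = []
    for fid in fold_ids:
        ids = [i for i, f in fold_of_image.items() if f == fid]
        excluded = [i for i in ids if grades[i] == ABSTAIN]
        included = [i for i in ids if grades[i] != ABSTAIN]
        correct = sum(1 for i in included if grades[i] == truths[i])
        out.append(FoldOutcome(fold_id=fid, n_included=len(included),
                               n_excluded=len(excluded),
                               n_correct_included=correct))
    return out


def beta_sweep(
    predictions_by_image: Mapping[str, Sequence[MemberPrediction]],
    betas: Sequence[float],
    truths: Mapping[str, int],
    fold_of_image: Mapping[str, int],
) -> pd.DataFrame:
    """WAA/AP as a function of beta, reusing cached member predictions.

    Members are not re-run per beta: the cached per-member distributions are
    re-gated at each threshold.  Rows are returned in ascending beta; since
    selections are nested under increasing beta, the AP column is
    non-increasing (asserted).
    """
    if len(betas) == 0:
        raise ValueError("betas must be non-empty")
    ds = len(predictions_by_image)
    rows = []
    for beta in sorted(betas):
        grades = {
            image_id: grade_predictions(preds, beta, image_id=image_id).grade
            for image_id, preds in predictions_by_image.items()
        }
        folds = fold_outcomes(grades, truths, fold_of_image)
        d_sum = sum(f.n_included for f in folds)
        rows.append({
            "beta": beta,
            "waa": waa(folds) if d_sum else np.nan,
            "ap": ap(folds, ds),
            "n_included": d_sum,
            "n_excluded": ds - d_sum,
        })
    table = pd.DataFrame(rows)
    assert (np.diff(table["ap"].to_numpy()) <= 1e-12).all(), \
        "AP must be non-increasing in beta"
    return table


DEFAULT_BETAS: tuple[float, ...] = tuple(np.logspace(-8, 0, 25)) + (1.25, 1.5, 1.75, 2.0)


def crossval_split(
    labels: Sequence[int],
    k: int = 5,
    seed: int = 0,
) -> list[np.ndarray]:
    """Stratified-by-grade k-fold test splits, deterministic given seed.

    Falls back to unstratified folds (with a warning) when some class has
    fewer than ``k`` images.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"class with only {counts.min()} images cannot be stratified into "
            f"{k} folds; falling back to unstratified split"
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(len(labels)), labels)]
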