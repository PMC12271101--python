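"""Slide-level metrics: kappa family, multiclass MCC, one-vs-rest curves.

Agreement between predicted and true fibrosis stages is scored per
cross-validation fold with Cohen's kappa (unweighted, linear, quadratic
over the ordinal stage ranks), the Gorodkin multiclass Matthews
correlation coefficient, and one-vs-rest AUROC/AUPRC computed from each
slide's patch-prediction ratio vector.  Fold rows are averaged into a
report with one row per fold plus an "Average" row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

METRIC_COLUMNS = ("kappa", "linear_kappa", "quadratic_kappa",
                  "mcc", "auroc", "auprc")


def confusion_matrix(
    true_idx: np.ndarray, pred_idx: np.ndarray, num_classes: int
) -> np.ndarray:
    """C x C counts, rows = true class, columns = predicted class."""
    true_idx = np.asarray(true_idx, dtype=int)
    pred_idx = np.asarray(pred_idx, dtype=int)
    if true_idx.shape != pred_idx.shape:
        raise ValueError("label vectors must have equal length")
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(cm, (true_idx, pred_idx), 1)
    return cm


def cohen_kappa(cm: np.ndarray, weighting: str = "none") -> float:
    """Chance-corrected agreement from a confusion matrix.

    kappa_w = 1 - sum(w_ij O_ij) / sum(w_ij E_ij) with disagreement
    weights w_ij = 1[i != j] (none), |i - j|/(C-1) (linear) or
    ((i - j)/(C-1))^2 (quadratic); E is the outer product of the
    marginals.  Class indices are the ordinal stage ranks.
    """
    cm = np.asarray(cm, dtype=np.float64)
    n = cm.sum()
    if n <= 0:
        raise ValueError("confusion matrix must contain at least one count")
    c = cm.shape[0]
    i, j = np.indices((c, c))
    if weighting == "none":
        w = (i != j).astype(float)
    elif weighting == "linear":
        w = np.abs(i - j) / (c - 1)
    elif weighting == "quadratic":
        w = ((i - j) / (c - 1)) ** 2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    expected = np.outer(cm.sum(axis=1), cm.sum(axis=0)) / n
    denom = (w * expected).sum()
    if denom == 0:
        warnings.warn(
            "degenerate marginals: chance-corrected agreement undefined, "
            "returning 0",
            stacklevel=2,
        )
        return 0.0
    return float(1.0 - (w * cm).sum() / denom)


def mcc_multiclass(cm: np.ndarray) -> float:
    """Generalized (Gorodkin) Matthews correlation from a confusion matrix.

    Reduces to the standard binary MCC for a 2x2 matrix.
    """
    cm = np.asarray(cm, dtype=np.float64)
    s = cm.sum()
    if s <= 0:
        raise ValueError("confusion matrix must contain at least one count")
    c = np.trace(cm)
    t = cm.sum(axis=1)  # true-class totals
    p = cm.sum(axis=0)  # predicted-class totals
    cov = c * s - t @ p
    var_t = s**2 - t @ t
    var_p = s**2 - p @ p
    if var_t == 0 or var_p == 0:
        warnings.warn(
            "zero-variance marginal: MCC undefined, returning 0", stacklevel=2
        )
        return 0.0
    return float(cov / np.sqrt(var_t * var_p))


def ovr_curves(
    ratio_vectors: np.ndarray, true_idx: np.ndarray, target: int
) -> tuple[float, float]:
    """One-vs-rest AUROC and AUPRC for one target class.

    The score of each slide is its patch-prediction ratio for the target
    class.  AUROC is the rank statistic (ties count 1/2); AUPRC is the
    step-wise (non-interpolated) average precision.
    """
    scores = np.asarray(ratio_vectors, dtype=float)[:, target]
    positive = np.asarray(true_idx) == target
    if positive.all() or not positive.any():
        raise ValueError(
            f"class {target}: need at least one positive and one negative slide"
        )
    return (
        float(roc_auc_score(positive, scores)),
        float(average_precision_score(positive, scores)),
    )


def macro_ovr(
    ratio_vectors: np.ndarray, true_idx: np.ndarray, num_classes: int
) -> tuple[float, float]:
    """Unweighted mean of per-class one-vs-rest AUROC/AUPRC.

    Classes absent from (or filling) the ground truth are skipped with a
    warning: their one-vs-rest split is undefined.
    """
    aurocs, auprcs = [], []
    true_idx = np.asarray(true_idx)
    for cls in range(num_classes):
        pos = int((true_idx == cls).sum())
        if pos == 0 or pos == len(true_idx):
            warnings.warn(
                f"class {cls} has no one-vs-rest split in this fold; skipped",
                stacklevel=2,
            )
            continue
        roc, pr = ovr_curves(ratio_vectors, true_idx, cls)
        aurocs.append(roc)
        auprcs.append(pr)
    if not aurocs:
        raise ValueError("no class admits a one-vs-rest evaluation")
    return float(np.mean(aurocs)), float(np.mean(auprcs))


@dataclass
class MetricReport:
    """Per-fold metric rows plus their unweighted fold average."""

    folds: pd.DataFrame  # one row per fold, METRIC_COLUMNS
    average: dict[str, float]

    def to_frame(self, decimals: int = 3) -> pd.DataFrame:
        """Report table: fold rows plus an "Average" row, rounded for
        display in the published column order."""
        disp = self.folds.copy()
        disp.insert(0, "fold", range(len(disp)))
        disp["fold"] = disp["fold"].astype(str)
        avg = {"fold": "Average", **self.average}
        out = pd.concat([disp, pd.DataFrame([avg])], ignore_index=True)
        out[list(METRIC_COLUMNS)] = out[list(METRIC_COLUMNS)].round(decimals)
        return out


def evaluate_fold(
    true_idx: np.ndarray,
    pred_idx: np.ndarray,
    ratio_vectors: np.ndarray,
    num_classes: int,
) -> dict[str, float]:
    """All six slide-level metrics for one validation fold."""
    cm = confusion_matrix(true_idx, pred_idx, num_classes)
    auroc, auprc = macro_ovr(ratio_vectors, true_idx, num_classes)
    return {
        "kappa": cohen_kappa(cm, "none"),
        "linear_kappa": cohen_kappa(cm, "linear"),
        "quadratic_kappa": cohen_kappa(cm, "quadratic"),
        "mcc": mcc_multiclass(cm),
        "auroc": auroc,
        "auprc": auprc,
    }


def average_metrics(fold_rows: list[dict[str, float]]) -> MetricReport:
    """Average per-fold metric rows (unweighted arithmetic mean).

    AUROC/AUPRC entries are expected to already be macro-averaged over
    classes within each fold; kappa and MCC are plain per-fold values.
    """
    if not fold_rows:
        raise ValueError("need at least one fold row")
    folds = pd.DataFrame(fold_rows)
    missing = [c for c in METRIC_COLUMNS if c not in folds.columns]
    if missing:
        raise ValueError(f"fold rows missing metrics: {missing}")
    folds = folds[list(METRIC_COLUMNS)]
    return MetricReport(folds=folds, average=folds.mean().to_dict())
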