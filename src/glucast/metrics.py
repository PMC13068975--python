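"""Regression, glycemic-classification and Clarke-Error-Grid evaluation.

A forecast run is scored three ways: continuous accuracy (RMSE, MAE, R^2 in
mg/dL), 3-class agreement after mapping both reference and forecast through
the glycemic thresholds (confusion matrix, generalized Matthews correlation,
per-class precision/recall/F1), and clinical risk via the Clarke Error Grid,
which partitions (reference, predicted) pairs into zones A (clinically
accurate) through E (dangerously wrong).

The CEG zone geometry follows the canonical Clarke (1987) piecewise
inequalities; rules are evaluated in the fixed order A, E, C, D, else B, and
the test suite pins the assignment against an independently coded reference
on a dense grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from .features import CLASSES, glycemic_label

ZONES = ("A", "B", "C", "D", "E")


@dataclass
class EvalReport:
    """All evaluation quantities for one forecast run."""

    rmse: float
    mae: float
    r2: float
    mcc: float
    per_class: dict[str, dict[str, float]]
    ceg_percent: dict[str, float]
    confusion: np.ndarray
    n: int

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "r2": self.r2,
            "mcc": self.mcc,
            "per_class": self.per_class,
            "ceg_percent": dict(self.ceg_percent),
            "confusion": self.confusion.tolist(),
            "n": self.n,
        }


def regression_metrics(y_true, y_pred) -> tuple[float, float, float]:
    """RMSE, MAE and R^2 (about the true mean) of aligned mg/dL sequences."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")
    rmse = float(np.sqrt(_skm.mean_squared_error(y_true, y_pred)))
    mae = float(_skm.mean_absolute_error(y_true, y_pred))
    if np.ptp(y_true) == 0:
        warnings.warn("R^2 undefined for constant y_true; reporting NaN")
        r2 = float("nan")
    else:
        r2 = float(_skm.r2_score(y_true, y_pred))
    return rmse, mae, r2


def confusion_matrix3(true_labels, pred_labels) -> np.ndarray:
    """3x3 counts, rows = true class, columns = predicted, in the fixed order
    (hypo, normal, hyper)."""
    index = {c: i for i, c in enumerate(CLASSES)}
    cm = np.zeros((3, 3), dtype=int)
    for t, p in zip(np.asarray(true_labels), np.asarray(pred_labels)):
        cm[index[str(t)], index[str(p)]] += 1
    return cm


def mcc_multiclass(cm: np.ndarray) -> float:
    """Generalized (multiclass) Matthews correlation from a confusion matrix.

    mcc = (c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))
    where c = trace, s = total, t_k/p_k = true/predicted counts of class k.
    A degenerate denominator (all one class) gives 0 with a warning."""
    cm = np.asarray(cm, dtype=float)
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    s = cm.sum()
    if s <= 0:
        raise ValueError("confusion matrix is empty")
    c = np.trace(cm)
    t = cm.sum(axis=1)
    p = cm.sum(axis=0)
    denom_sq = (s**2 - (p**2).sum()) * (s**2 - (t**2).sum())
    if denom_sq <= 0:
        warnings.warn("degenerate confusion matrix; MCC reported as 0")
        return 0.0
    return float((c * s - (p * t).sum()) / np.sqrt(denom_sq))


def class_metrics(cm: np.ndarray) -> dict[str, dict[str, float]]:
    """Per-class precision, recall and F1; zero denominators give 0."""
    cm = np.asarray(cm, dtype=float)
    out: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(CLASSES):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        if precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            f1 = 0.0
            if tp + fp == 0 or tp + fn == 0:
                warnings.warn(f"zero denominator for class {cls}")
        out[cls] = {"precision": float(precision), "recall": float(recall), "f1": float(f1)}
    return out


def ceg_zone(reference: float, predicted: float) -> str:
    """Clarke Error Grid zone of one (reference, predicted) pair, mg/dL.

    First matching rule wins, in the order A, E, C, D; everything else is B."""
    r, p = float(reference), float(predicted)
    if not (0 < r <= 600 and 0 < p <= 600):
        raise ValueError("glucose values must be in (0, 600] mg/dL")
    if (r <= 70 and p <= 70) or abs(p - r) <= 0.2 * r:
        return "A"
    if (r >= 180 and p <= 70) or (r <= 70 and p >= 180):
        return "E"
    if (70 <= r <= 290 and p >= r + 110) or (130 <= r <= 180 and p <= (7.0 / 5.0) * r - 182):
        return "C"
    if (
        (r >= 240 and 70 <= p <= 180)
        or (r <= 175.0 / 3.0 and 70 <= p <= 180)
        or (175.0 / 3.0 <= r <= 70 and p >= (6.0 / 5.0) * r)
    ):
        return "D"
    return "B"


def ceg_zones(reference, predicted) -> np.ndarray:
    return np.array([ceg_zone(r, p) for r, p in zip(reference, predicted)])


def ceg_percentages(reference, predicted) -> dict[str, float]:
    """Percentage of points per zone; sums to 100."""
    zones = ceg_zones(reference, predicted)
    n = len(zones)
    if n == 0:
        raise ValueError("no points for CEG analysis")
    return {z: float(100.0 * np.sum(zones == z) / n) for z in ZONES}


def evaluate_forecasts(
    y_true,
    y_pred,
    originally_observed_mask=None,
) -> EvalReport:
    """Full evaluation of aligned truth/forecast sequences in mg/dL.

    When a mask of originally observed slots is given (the inference pipeline
    fills gaps before forecasting), every metric is computed only over masked
    points, so scores never reward agreement with interpolated pseudo-truth."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be aligned")
    if originally_observed_mask is not None:
        m = np.asarray(originally_observed_mask, dtype=bool)
        if m.shape != y_true.shape:
            raise ValueError("mask must align with the sequences")
        y_true, y_pred = y_true[m], y_pred[m]
    if y_true.size == 0:
        raise ValueError("no originally observed points to evaluate")
    rmse, mae, r2 = regression_metrics(y_true, y_pred)
    cm = confusion_matrix3(glycemic_label(y_true), glycemic_label(y_pred))
    return EvalReport(
        rmse=rmse,
        mae=mae,
        r2=r2,
        mcc=mcc_multiclass(cm),
        per_class=class_metrics(cm),
        ceg_percent=ceg_percentages(y_true, y_pred),
        confusion=cm,
        n=int(y_true.size),
    )
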