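"""Binary classification scoring: confusion-matrix rates, ROC/AUC, k-fold CV.

The positive class throughout is the death outcome (label 1).  AUC is
computed by an explicit threshold sweep with trapezoidal integration,
which equals the Mann-Whitney concordance probability (ties counted 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .trainer import TrainerConfig, train

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "roc_curve",
    "roc_auc",
    "auc_p_value",
    "stratified_folds",
    "cross_validate",
    "CrossValidationResult",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-matrix rates; a rate with a zero denominator is None."""

    acc: Optional[float]
    tpr: Optional[float]  # recall / sensitivity
    fpr: Optional[float]
    tnr: Optional[float]  # specificity
    pre: Optional[float]
    f1: Optional[float]
    gm: Optional[float]  # sqrt(tpr * tnr)
    auc: Optional[float] = None

    def as_dict(self) -> dict:
        return asdict(self)


def _check_binary(y: np.ndarray, what: str) -> np.ndarray:
    y = np.asarray(y)
    values = set(np.unique(y).tolist())
    if not values <= {0, 1}:
        raise ValueError(f"{what} must be binary 0/1 labels, got values {sorted(values)}")
    return y.astype(int)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Standard counts with label 1 as the positive class."""
    y_true = _check_binary(np.asarray(y_true), "y_true")
    y_pred = _check_binary(np.asarray(y_pred), "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    acc = _ratio(cm.tp + cm.tn, cm.total)
    tpr = _ratio(cm.tp, cm.tp + cm.fn)
    fpr = _ratio(cm.fp, cm.fp + cm.tn)
    tnr = None if fpr is None else 1.0 - fpr
    pre = _ratio(cm.tp, cm.tp + cm.fp)
    f1 = None
    if pre is not None and tpr is not None:
        f1 = 0.0 if pre + tpr == 0 else 2.0 * pre * tpr / (pre + tpr)
    gm = None if tpr is None or tnr is None else float(np.sqrt(tpr * tnr))
    return MetricsReport(acc=acc, tpr=tpr, fpr=fpr, tnr=tnr, pre=pre, f1=f1, gm=gm)


def roc_curve(y_true: Sequence[int], scores: Sequence[float]) -> np.ndarray:
    """ROC points as an array of (fpr, tpr, threshold) rows.

    One point per unique score value (predicting positive when
    score >= threshold), plus the (0, 0) and (1, 1) endpoints.
    """
    y_true = _check_binary(np.asarray(y_true), "y_true")
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = y_true[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # keep the last index of each tied-score run
    last_of_run = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = tps[last_of_run] / n_pos
    fpr = fps[last_of_run] / n_neg
    thresholds = sorted_scores[last_of_run]
    points = np.column_stack(
        [np.r_[0.0, fpr], np.r_[0.0, tpr], np.r_[np.inf, thresholds]]
    )
    return points


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> tuple[np.ndarray, float]:
    """ROC points and the trapezoidal area under the curve."""
    points = roc_curve(y_true, scores)
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return points, auc


def auc_p_value(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Two-sided Mann-Whitney test of score separation between the classes."""
    y_true = _check_binary(np.asarray(y_true), "y_true")
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes for the score-separation test")
    return float(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)


def stratified_folds(
    y: Sequence[int], k: int = 5, seed: Optional[int] = None
) -> list[np.ndarray]:
    """Index arrays for k folds preserving the class balance.

    Every index appears in exactly one fold; fold sizes differ by at most
    one per class.  Raises when either class has fewer than ``k`` members.
    """
    y = _check_binary(np.asarray(y), "y")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for label in (0, 1):
        idx = np.flatnonzero(y == label)
        if len(idx) < k:
            raise ValueError(f"class {label} has only {len(idx)} members; cannot make {k} folds")
        rng.shuffle(idx)
        chunks = np.array_split(idx, k)
        if label == 1:  # spread per-class remainders so fold sizes differ by <= 1
            chunks = chunks[::-1]
        for fold_id, chunk in enumerate(chunks):
            folds[fold_id].extend(chunk.tolist())
    return [np.sort(np.array(f)) for f in folds]


@dataclass
class CrossValidationResult:
    fold_reports: list[MetricsReport]
    fold_roc: list[np.ndarray]
    mean_report: MetricsReport
    fold_indices: list[np.ndarray]

    def as_dict(self) -> dict:
        return {
            "folds": [r.as_dict() for r in self.fold_reports],
            "mean": self.mean_report.as_dict(),
        }


def _mean_reports(reports: list[MetricsReport]) -> MetricsReport:
    def agg(attr):
        values = [getattr(r, attr) for r in reports if getattr(r, attr) is not None]
        return float(np.mean(values)) if values else None

    return MetricsReport(
        **{k: agg(k) for k in ("acc", "tpr", "fpr", "tnr", "pre", "f1", "gm", "auc")}
    )


def cross_validate(
    X: np.ndarray,
    y: Sequence[int],
    trainer_config: TrainerConfig,
    k: int = 5,
    seed: Optional[int] = None,
) -> CrossValidationResult:
    """Stratified k-fold evaluation of the swarm-trained network.

    Each fold trains on the remaining k-1 folds (standardization fitted on
    the training part only) and is scored on the held-out records; the
    aggregate is the unweighted mean of fold metrics.
    """
    X = np.asarray(X, dtype=float)
    y = _check_binary(np.asarray(y), "y")
    folds = stratified_folds(y, k=k, seed=seed)
    reports: list[MetricsReport] = []
    rocs: list[np.ndarray] = []
    for fold_id, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        model, _ = train(X[train_mask], y[train_mask], trainer_config)
        scores = model.predict_proba(X[test_idx])
        preds = (scores >= 0.5).astype(int)
        report = metrics(confusion(y[test_idx], preds))
        points, auc = roc_auc(y[test_idx], scores)
        reports.append(MetricsReport(**{**report.as_dict(), "auc": auc}))
        rocs.append(points)
    return CrossValidationResult(
        fold_reports=reports,
        fold_roc=rocs,
        mean_report=_mean_reports(reports),
        fold_indices=folds,
    )
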