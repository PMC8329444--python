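"""Evaluation metrics for imbalanced placental-transfer classification.

The positive class is NC (does not cross the placenta, the minority class);
the negative class is C (crosses, the majority). The working score is the
F_beta score with beta = 1/2, which weights precision over recall and thereby
penalizes predicting a crossing compound as non-crossing (a false positive
under this convention) — the costly mistake for a prenatal-safety filter.

Precision or recall with a zero denominator is *undefined*, not zero. Reports
carry the undefined marker (``None``); only :func:`f_beta` maps an undefined
ratio to a score of 0, so that optimization over candidate models has a total
order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve as _sk_pr_curve

POSITIVE_LABEL = "NC"
NEGATIVE_LABEL = "C"
VALID_LABELS = frozenset({POSITIVE_LABEL, NEGATIVE_LABEL})


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts under the fixed positive = NC convention."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> Optional[float]:
        if self.n == 0:
            return None
        return (self.tp + self.tn) / self.n


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall points at descending score thresholds.

    ``precision[i]`` and ``recall[i]`` are the values obtained when every
    sample scoring at least ``thresholds[i]`` is predicted positive; recall is
    non-decreasing along the arrays.
    """

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.thresholds) == len(self.precision) == len(self.recall)):
            raise ValueError("curve arrays must be aligned")
        if np.any(np.diff(self.recall) < 0):
            raise ValueError("recall must be non-decreasing as the threshold falls")


def _validate_labels(labels: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    bad = set(arr) - VALID_LABELS
    if bad:
        raise ValueError(f"{what} contains labels outside {{C, NC}}: {sorted(bad)}")
    return arr


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> ConfusionCounts:
    """Count TP/FP/FN/TN with NC as the positive class."""
    yt = _validate_labels(true_labels, "true_labels")
    yp = _validate_labels(predicted_labels, "predicted_labels")
    if len(yt) != len(yp):
        raise ValueError(f"length mismatch: {len(yt)} true vs {len(yp)} predicted")
    tpos = yt == POSITIVE_LABEL
    ppos = yp == POSITIVE_LABEL
    return ConfusionCounts(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
    )


def precision_recall_fpr(
    counts: ConfusionCounts,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Precision, recall and false-positive rate; ``None`` where undefined."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    fpr = counts.fp / (counts.fp + counts.tn) if counts.fp + counts.tn > 0 else None
    return p, r, fpr


def f_beta(counts: ConfusionCounts, beta: float = 0.5) -> float:
    """Weighted harmonic mean of precision and recall.

    F_beta = (1 + beta^2) P R / (beta^2 P + R). Returns 0 when either ratio is
    undefined or both are zero, so the score totally orders candidate models.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    p, r, _ = precision_recall_fpr(counts)
    if p is None or r is None or (p == 0 and r == 0):
        return 0.0
    b2 = beta * beta
    return (1 + b2) * p * r / (b2 * p + r)


def pr_curve(scores: Sequence[float], true_labels: Sequence[str]) -> PRCurve:
    """Precision-recall curve over every distinct score threshold."""
    yt = _validate_labels(true_labels, "true_labels")
    s = np.asarray(scores, dtype=float)
    if len(s) != len(yt):
        raise ValueError(f"length mismatch: {len(s)} scores vs {len(yt)} labels")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    y = (yt == POSITIVE_LABEL).astype(int)
    if y.sum() == 0:
        raise ValueError("pr_curve undefined without positive samples")
    prec, rec, thr = _sk_pr_curve(y, s)
    # drop the appended (P=1, R=0) endpoint, reverse so thresholds descend
    return PRCurve(
        thresholds=thr[::-1].copy(),
        precision=prec[:-1][::-1].copy(),
        recall=rec[:-1][::-1].copy(),
    )


def average_precision(curve: PRCurve) -> float:
    """Riemann-style PR-curve summary: sum of P_n (R_n - R_{n-1}), R_0 = 0."""
    r_prev = np.concatenate([[0.0], curve.recall[:-1]])
    return float(np.sum(curve.precision * (curve.recall - r_prev)))


def metrics_report(
    counts: ConfusionCounts,
    scores: Optional[Sequence[float]] = None,
    true_labels: Optional[Sequence[str]] = None,
    beta: float = 0.5,
) -> dict:
    """JSON-ready metric summary; undefined ratios serialize as null."""
    p, r, fpr = precision_recall_fpr(counts)
    report = {
        "tp": counts.tp,
        "fp": counts.fp,
        "fn": counts.fn,
        "tn": counts.tn,
        "precision": p,
        "recall": r,
        "fpr": fpr,
        "f_half": f_beta(counts, beta) if (p is not None and r is not None) else None,
        "accuracy": counts.accuracy,
        "average_precision": None,
    }
    if scores is not None and true_labels is not None:
        report["average_precision"] = average_precision(pr_curve(scores, true_labels))
    return report
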