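"""Metric suite for ordinal lameness grading and binary screening.

The 7-grade task is scored with balanced accuracy (unweighted mean of
per-true-class recall), relaxed accuracy (within one grade), mean
squared error on the ordinal scale, and class-frequency-weighted recall
and precision.  Binary screening maps grades 1-3 to healthy and 6-7 to
lame; the borderline grades 4-5 are excluded from binary evaluation
because they carry the worst inter-observer agreement.  Inter-rater
agreement uses unweighted Cohen's kappa (grade tolerance is already
carried by relaxed accuracy).

Predictions may contain the merged 4-5 ordinal (4.5): it is exactly
half a grade from both true 4 and true 5 (within the relaxed margin,
contributing 0.25 to the MSE) and 1.5 grades from a true 3 (a miss).

Metrics are implemented directly so the merged ordinal is handled
uniformly; scikit-learn's implementations serve as an independent
cross-check in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("bovigait")

__all__ = [
    "EvaluationReport",
    "relaxed_accuracy",
    "balanced_accuracy",
    "mse",
    "binary_map",
    "cohens_kappa",
    "evaluate",
    "HEALTHY",
    "LAME",
]

HEALTHY, LAME = "healthy", "lame"
_TOL = 1e-9  # |pred - true| <= 1 up to float noise


@dataclass
class EvaluationReport:
    task: str
    balanced_accuracy: float
    accuracy: float
    recall: float
    precision: float
    n_evaluated: int
    n_excluded: int = 0
    relaxed_accuracy: float | None = None  # grade7 only
    mse: float | None = None  # grade7 only

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def _check_lengths(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(y_true)
    b = np.asarray(y_pred)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty input")
    return a, b


def relaxed_accuracy(y_true, y_pred) -> float:
    """Fraction of predictions within one grade of the truth."""
    a, b = _check_lengths(y_true, y_pred)
    return float(np.mean(np.abs(b.astype(float) - a.astype(float)) <= 1.0 + _TOL))


def balanced_accuracy(y_true, y_pred) -> float:
    """Unweighted mean of per-true-class recall."""
    a, b = _check_lengths(y_true, y_pred)
    recalls = []
    for cls in np.unique(a):
        sel = a == cls
        recalls.append(np.mean(b[sel] == cls))
    return float(np.mean(recalls))


def mse(y_true, y_pred) -> float:
    """Mean squared ordinal difference."""
    a, b = _check_lengths(y_true, y_pred)
    return float(np.mean((b.astype(float) - a.astype(float)) ** 2))


def binary_map(grades) -> tuple[np.ndarray, np.ndarray]:
    """Grades -> (labels, evaluated mask): 1-3 healthy, 6-7 lame, 4-5 excluded."""
    g = np.asarray(grades)
    if np.any((g < 1) | (g > 7)):
        raise ValueError("grades must be within 1..7")
    labels = np.where(g <= 3, HEALTHY, LAME)
    mask = (g <= 3) | (g >= 6)
    return labels, mask


def cohens_kappa(ratings_a, ratings_b) -> float:
    """Unweighted Cohen's kappa: (p_o - p_e) / (1 - p_e).

    When both raters are constant and identical (p_e = 1), agreement is
    perfect and 1.0 is returned by convention.
    """
    a, b = _check_lengths(ratings_a, ratings_b)
    cats = np.unique(np.concatenate([a, b]))
    n = a.size
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        logger.info("both raters constant and equal; kappa = 1 by convention")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def _weighted_recall_precision(y_true, y_pred) -> tuple[float, float]:
    """Class-frequency-weighted recall and precision.

    Precision of a class never predicted is 0 (logged), so the weighted
    figure stays defined for degenerate predictors.
    """
    a, b = _check_lengths(y_true, y_pred)
    classes = np.unique(a)
    n = a.size
    recall = 0.0
    precision = 0.0
    for cls in classes:
        t_sel = a == cls
        p_sel = b == cls
        w = t_sel.sum() / n
        recall += w * float(np.mean(b[t_sel] == cls))
        if p_sel.sum() == 0:
            logger.info("class %r never predicted; its precision counts as 0", cls)
            continue
        precision += w * float(np.mean(a[p_sel] == cls))
    return recall, precision


def evaluate(y_true, y_pred, task: str = "grade7") -> EvaluationReport:
    """Assemble the metric suite for one prediction set.

    For ``grade7``, ``y_true`` holds grades 1..7 and ``y_pred`` ordinals
    (the merged 4.5 allowed).  For ``binary``, ``y_true`` holds grades
    and ``y_pred`` healthy/lame labels aligned with the full grade
    vector; grade 4-5 rows are excluded here and counted.
    """
    if task == "grade7":
        a, b = _check_lengths(y_true, y_pred)
        rec, prec = _weighted_recall_precision(a.astype(float), b.astype(float))
        return EvaluationReport(
            task=task,
            balanced_accuracy=balanced_accuracy(a.astype(float), b.astype(float)),
            accuracy=float(np.mean(a.astype(float) == b.astype(float))),
            recall=rec,
            precision=prec,
            n_evaluated=int(a.size),
            relaxed_accuracy=relaxed_accuracy(a, b),
            mse=mse(a, b),
        )
    if task == "binary":
        a, b = _check_lengths(y_true, y_pred)
        true_labels, mask = binary_map(a)
        t = true_labels[mask]
        p = np.asarray(b)[mask]
        if t.size == 0:
            raise ValueError("no rows left after excluding grades 4-5")
        pos_t = t == LAME
        pos_p = p == LAME
        recall = float(np.mean(pos_p[pos_t])) if pos_t.any() else 0.0
        precision = float(np.mean(pos_t[pos_p])) if pos_p.any() else 0.0
        return EvaluationReport(
            task=task,
            balanced_accuracy=balanced_accuracy(t, p),
            accuracy=float(np.mean(t == p)),
            recall=recall,
            precision=precision,
            n_evaluated=int(t.size),
            n_excluded=int((~mask).sum()),
        )
    raise ValueError(f"unknown task {task!r}")
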