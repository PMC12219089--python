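"""Binary classification metrics from a single score: ROC, AUC, accuracy.

Used to judge how well one NMF component separates two classes.  Ties
in score are handled by threshold grouping (all equal scores cross a
threshold together); the trapezoidal AUC then coincides with the
tie-corrected Mann-Whitney rank statistic.  Because an NMF component's
scale and orientation are arbitrary, the best-threshold accuracy scan
considers both orientations.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

__all__ = ["roc_curve", "auc", "best_threshold_accuracy"]


def _check(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 1 or labels.shape != scores.shape:
        raise ValueError("scores and labels must be 1-D and of equal length")
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly two classes present, got {uniq.size}")
    pos = labels == uniq.max()
    return scores, pos.astype(bool)


def roc_curve(scores, labels) -> np.ndarray:
    """ROC points (false-positive rate, true-positive rate).

    Thresholds are the distinct score values (descending) plus a
    sentinel above the maximum; a sample is called positive when its
    score is >= the threshold, so tied scores enter together.  The
    curve starts at (0, 0), ends at (1, 1), and is monotone
    non-decreasing in both coordinates.

    Returns an (n_thresholds + 1, 2) array of (fpr, tpr) rows.
    """
    scores, pos = _check(scores, labels)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = pos[order]
    tp = np.cumsum(p)
    fp = np.cumsum(~p)
    # keep only the last index of each tied block of scores
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    return np.column_stack([fpr, tpr])


def auc(scores, labels) -> float:
    """Area under the ROC curve (trapezoidal rule).

    Equals the tie-corrected rank statistic: the probability that a
    random positive outscores a random negative, with half credit for
    ties.
    """
    pts = roc_curve(scores, labels)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def best_threshold_accuracy(scores, labels) -> Tuple[float, float]:
    """Exhaustive best-accuracy threshold over both orientations.

    Scans midpoints between consecutive distinct sorted scores (plus
    sentinels beyond the extremes), classifying positive when
    score >= t (and score <= t for the reversed orientation).  Returns
    ``(threshold, accuracy)``; ties are resolved in favour of the
    lowest threshold with the positive-high orientation.
    """
    scores, pos = _check(scores, labels)
    n = scores.size
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.r_[distinct[0] - 1.0, mids, distinct[-1] + 1.0]
    best_acc = -1.0
    best_t = thresholds[0]
    for t in thresholds:  # positive-high orientation first (wins ties)
        acc = float(((scores >= t) == pos).mean())
        if acc > best_acc:
            best_acc, best_t = acc, float(t)
    for t in thresholds:
        acc = float(((scores <= t) == pos).mean())
        if acc > best_acc:
            best_acc, best_t = acc, float(t)
    return best_t, best_acc
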