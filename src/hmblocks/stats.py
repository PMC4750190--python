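"""Shared statistical helpers: rank-sum comparison and AUC utilities."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

#: per-group size at or below which the exact rank-sum null is enumerated
EXACT_RANKSUM_LIMIT = 50


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney (Wilcoxon rank-sum) U statistic and p-value.

    Exact enumeration of the null is used for small untied samples; larger
    or tied samples fall back to the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("rank-sum comparison needs at least 2 values per group")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(x), len(y)) <= EXACT_RANKSUM_LIMIT
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC curve (FPR, TPR, thresholds) over descending score thresholds.

    Returns arrays beginning at (0, 0) and ending at (1, 1); thresholds are
    the distinct score values, aligned with the curve points after the
    origin.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(~sorted_labels)
    # collapse runs of equal scores to a single operating point
    distinct = np.flatnonzero(np.diff(sorted_scores, append=-np.inf))
    tpr = np.concatenate([[0.0], tp[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fp[distinct] / n_neg])
    thresholds = np.concatenate([[np.inf], sorted_scores[distinct]])
    return fpr, tpr, thresholds


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Area under an ROC curve by the trapezoidal rule."""
    return float(np.trapezoid(tpr, fpr))


def auc_mannwhitney(scores, labels) -> float:
    """AUC via the Mann-Whitney U relation (rank-based, tie-averaged)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))
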