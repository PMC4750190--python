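"""Random-forest discrimination of boundary regions from control classes.

The forest is a bagging ensemble of unpruned CART trees (scikit-learn
``DecisionTreeClassifier``) with ``m`` features sampled per split and a
majority vote over trees. Bootstrapping is done here rather than inside
scikit-learn so that each tree's out-of-bag (OOB) rows are known exactly:
that gives the OOB error used to tune ``m`` and the *mean decrease accuracy*
(MDA) permutation importance — for each tree, the drop in OOB accuracy when
one feature's values are shuffled, averaged over trees.

Evaluation follows a random stratified 70–30 train/test split. Sensitivity,
specificity and F-measure are reported at the threshold over the vote
fraction that maximizes F on the held-out split (an optimistic choice by
construction, and logged as such); AUC is the trapezoidal area under the ROC
of vote fractions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .motifs import FeatureMatrix
from .stats import auc_trapezoid, roc_points

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ForestSpec:
    n_trees: int = 500
    m: int | None = None  # None -> n_features // 3
    seed: int = 0

    def resolved_m(self, n_features: int) -> int:
        m = self.m if self.m is not None else max(1, n_features // 3)
        if not 1 <= m <= n_features:
            raise ValueError(f"m={m} outside [1, {n_features}]")
        return m


@dataclass
class ClassifierReport:
    positive_label: str
    negative_label: str
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    auc: float
    threshold: float
    confusion: dict[str, int]  # tp, fp, tn, fn on the held-out split
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    importances: pd.Series | None  # MDA per feature, None for margin models
    oob_error: float | None = None
    m_used: int | None = None

    def __post_init__(self) -> None:
        tp, fp = self.confusion["tp"], self.confusion["fp"]
        fn = self.confusion["fn"]
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        expect_f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        if abs(expect_f - self.f_measure) > 1e-9:
            raise ValueError("f_measure is not the harmonic mean of precision/recall")

    def to_json(self, path: str | Path) -> None:
        payload = {
            k: getattr(self, k)
            for k in (
                "positive_label",
                "negative_label",
                "sensitivity",
                "specificity",
                "precision",
                "f_measure",
                "auc",
                "threshold",
                "confusion",
                "oob_error",
                "m_used",
            )
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


class _BaggedForest:
    """Bagging ensemble with explicit bootstrap bookkeeping."""

    def __init__(self, n_trees: int, m: int, rng: np.random.Generator):
        self.n_trees = n_trees
        self.m = m
        self.rng = rng
        self.trees: list[DecisionTreeClassifier] = []
        self.oob_masks: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaggedForest":
        n = len(y)
        for _ in range(self.n_trees):
            idx = self.rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeClassifier(
                max_features=self.m,
                random_state=int(self.rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees.append(tree)
            self.oob_masks.append(oob)
        self._X, self._y = X, y
        return self

    def vote_fraction(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros(len(X))
        for tree in self.trees:
            votes += tree.predict(X)
        return votes / self.n_trees

    def oob_error(self) -> float:
        n = len(self._y)
        votes = np.zeros(n)
        counts = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_masks):
            if oob.any():
                votes[oob] += tree.predict(self._X[oob])
                counts[oob] += 1
        seen = counts > 0
        pred = votes[seen] / counts[seen] > 0.5
        return float(np.mean(pred != self._y[seen].astype(bool)))

    def mean_decrease_accuracy(self, rng: np.random.Generator) -> np.ndarray:
        """Per-feature MDA: mean over trees of OOB accuracy minus OOB
        accuracy after permuting that feature's values among OOB rows."""
        n_features = self._X.shape[1]
        drops = np.zeros((self.n_trees, n_features))
        for t, (tree, oob) in enumerate(zip(self.trees, self.oob_masks)):
            if not oob.any():
                continue
            Xo, yo = self._X[oob], self._y[oob]
            base_acc = float(np.mean(tree.predict(Xo) == yo))
            for f in range(n_features):
                perm = rng.permutation(len(yo))
                Xp = Xo.copy()
                Xp[:, f] = Xo[perm, f]
                drops[t, f] = base_acc - float(np.mean(tree.predict(Xp) == yo))
        return drops.mean(axis=0)


def _labels_to_binary(features: FeatureMatrix, positive_label: str | None):
    classes = features.classes()
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if positive_label is None:
        positive_label = "boundary" if "boundary" in classes else classes[0]
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not among {classes}")
    negative_label = next(c for c in classes if c != positive_label)
    y = (features.labels == positive_label).to_numpy()
    return y, positive_label, negative_label


def tune_m(
    features: FeatureMatrix,
    spec: ForestSpec = ForestSpec(),
    grid: Sequence[int] | None = None,
) -> int:
    """Choose ``m`` (features sampled per split) by out-of-bag error over a
    grid around n_features/3; ties break toward smaller m."""
    y, _, _ = _labels_to_binary(features, None)
    X = features.counts.to_numpy(dtype=float)
    n_features = X.shape[1]
    if grid is None:
        base = max(1, n_features // 3)
        grid = sorted(
            {max(1, min(n_features, int(round(base * f)))) for f in (0.25, 0.5, 0.75, 1.0, 1.5, 2.0)}
        )
    ss = np.random.SeedSequence([spec.seed, 0x7A0E])
    best_m, best_err = None, np.inf
    for m, child in zip(grid, ss.spawn(len(list(grid)))):
        forest = _BaggedForest(spec.n_trees, m, np.random.default_rng(child))
        forest.fit(X, y)
        err = forest.oob_error()
        log.info("tune_m: m=%d oob_error=%.4f", m, err)
        if err < best_err - 1e-12:
            best_m, best_err = m, err
    return int(best_m)


def _operating_point(scores: np.ndarray, y: np.ndarray):
    """F-measure-optimal threshold over the score values (>= threshold is
    called positive); returns threshold and the confusion counts there."""
    fpr, tpr, thresholds = roc_points(scores, y)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    best = None
    for fp_rate, tp_rate, thr in zip(fpr[1:], tpr[1:], thresholds[1:]):
        tp = tp_rate * n_pos
        fp = fp_rate * n_neg
        fn = n_pos - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / n_pos
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        if best is None or f > best[0] + 1e-12:
            best = (f, thr, int(round(tp)), int(round(fp)))
    f, thr, tp, fp = best
    fn = n_pos - tp
    tn = n_neg - fp
    return thr, {"tp": tp, "fp": fp, "tn": tn, "fn": fn}


def _report_from_scores(
    scores: np.ndarray,
    y: np.ndarray,
    positive_label: str,
    negative_label: str,
    importances: pd.Series | None,
    oob_error: float | None = None,
    m_used: int | None = None,
) -> ClassifierReport:
    fpr, tpr, thresholds = roc_points(scores, y)
    auc = auc_trapezoid(fpr, tpr)
    thr, confusion = _operating_point(scores, y)
    tp, fp, tn, fn = (confusion[k] for k in ("tp", "fp", "tn", "fn"))
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f_measure = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return ClassifierReport(
        positive_label=positive_label,
        negative_label=negative_label,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f_measure=f_measure,
        auc=auc,
        threshold=float(thr),
        confusion=confusion,
        roc=roc,
        importances=importances,
        oob_error=oob_error,
        m_used=m_used,
    )


def train_evaluate(
    features: FeatureMatrix,
    split: SplitSpec = SplitSpec(),
    spec: ForestSpec = ForestSpec(),
    positive_label: str | None = None,
) -> ClassifierReport:
    """Fit the forest on the training split, evaluate on the held-out split.

    Importances are OOB permutation MDA from the training forest. Split,
    forest bootstrap and permutation randomness use separate substreams of
    the two seeds so each is independently reproducible.
    """
    y, pos, neg = _labels_to_binary(features, positive_label)
    X = features.counts.to_numpy(dtype=float)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=split.train_fraction,
        random_state=split.seed,
        stratify=y,
    )
    if len(set(y[train_idx])) < 2:
        raise ValueError("a class is absent from the training split")
    m = spec.resolved_m(X.shape[1])
    ss = np.random.SeedSequence([spec.seed, 240])
    forest_rng, perm_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    forest = _BaggedForest(spec.n_trees, m, forest_rng).fit(X[train_idx], y[train_idx])
    scores = forest.vote_fraction(X[test_idx])
    mda = forest.mean_decrease_accuracy(perm_rng)
    importances = pd.Series(mda, index=features.counts.columns, name="mda")
    return _report_from_scores(
        scores,
        y[test_idx],
        pos,
        neg,
        importances,
        oob_error=forest.oob_error(),
        m_used=m,
    )


def train_evaluate_margin(
    features: FeatureMatrix,
    split: SplitSpec = SplitSpec(),
    positive_label: str | None = None,
) -> ClassifierReport:
    """Max-margin (SVM) replication of the discrimination task under 10-fold
    cross-validation; same report contract, no importances."""
    y, pos, neg = _labels_to_binary(features, positive_label)
    X = features.counts.to_numpy(dtype=float)
    scores = np.zeros(len(y))
    folds = StratifiedKFold(n_splits=10, shuffle=True, random_state=split.seed)
    for train_idx, test_idx in folds.split(X, y):
        if len(set(y[train_idx])) < 2:
            raise ValueError("a class is absent from a training fold")
        model = SVC(kernel="rbf", gamma="scale")
        model.fit(X[train_idx], y[train_idx])
        scores[test_idx] = model.decision_function(X[test_idx])
    return _report_from_scores(scores, y, pos, neg, importances=None)


def rank_importances(report: ClassifierReport, k: int) -> list[str]:
    """Top-k features by mean decrease accuracy, descending; ties break
    lexicographically by feature id."""
    if report.importances is None:
        raise ValueError("report carries no importances")
    if k > len(report.importances):
        raise ValueError(f"k={k} exceeds feature count {len(report.importances)}")
    order = sorted(
        report.importances.items(), key=lambda kv: (-kv[1], kv[0])
    )
    return [name for name, _ in order[:k]]
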