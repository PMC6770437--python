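"""Evaluation: classification metrics, AUC, segmentation overlap scores,
repeated stratified cross-validation, and one-way ANOVA.

The cross-validation protocol is 5 folds x 10 repeats (50 records), with
stratified folds re-drawn per repeat from seeds derived from one master
seed.  Any preprocessing that learns from data (PCA here) is fit inside
each training fold only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .reduction import pca_fit, pca_transform

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Confusion-matrix metrics

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        p = y_true == positive
        pp = y_pred == positive
        return cls(tp=int(np.sum(p & pp)), tn=int(np.sum(~p & ~pp)),
                   fp=int(np.sum(~p & pp)), fn=int(np.sum(p & ~pp)))


def classification_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, precision, sensitivity).

    Precision is defined as 0 when no positives are predicted, and
    sensitivity as 0 when no positives exist; both degenerate paths are
    logged.
    """
    if counts.total == 0:
        raise ValueError("no evaluated instances")
    acc = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp == 0:
        log.info("precision undefined (no predicted positives); returning 0")
        precision = 0.0
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        log.info("sensitivity undefined (no positive instances); returning 0")
        sensitivity = 0.0
    else:
        sensitivity = counts.tp / (counts.tp + counts.fn)
    return acc, precision, sensitivity


def auc(scores, labels, positive=None) -> float:
    """Rank-based AUC: P(score_pos > score_neg), ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if positive is None:
        positive = classes[-1]
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# --------------------------------------------------------------------------
# Segmentation overlap scores

@dataclass(frozen=True)
class SegmentationScores:
    dice: float
    jaccard: float
    specificity: float
    sensitivity: float
    accuracy: float
    precision: float


def segmentation_scores(pred, truth) -> SegmentationScores:
    """Pixelwise overlap scores between a predicted and ground-truth mask."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))

    def safe(num, den):
        return num / den if den > 0 else 0.0

    return SegmentationScores(
        dice=safe(2 * tp, 2 * tp + fp + fn),
        jaccard=safe(tp, tp + fp + fn),
        specificity=safe(tn, tn + fp),
        sensitivity=safe(tp, tp + fn),
        accuracy=safe(tp + tn, tp + tn + fp + fn),
        precision=safe(tp, tp + fp),
    )


# --------------------------------------------------------------------------
# Repeated stratified cross-validation

@dataclass
class CVResult:
    records: list[dict]  # one per repeat x fold: acc/precision/sensitivity/auc
    fold_assignments: np.ndarray  # (repeats, n_samples) fold index per instance
    seeds: list[int]
    folds: int
    repeats: int

    def metric(self, name: str) -> np.ndarray:
        return np.array([r[name] for r in self.records])

    def summary(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name in ("acc", "precision", "sensitivity", "auc"):
            v = self.metric(name)
            out[name] = (float(v.mean()), float(v.std(ddof=1)))
        return out

    def repeat_means(self, name: str = "acc") -> np.ndarray:
        """Per-repeat mean of a metric (the ANOVA grouping unit)."""
        v = self.metric(name).reshape(self.repeats, self.folds)
        return v.mean(axis=1)


def _stratified_folds(y, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per instance; class ratios within +-1 of the global ratio."""
    y = np.asarray(y)
    assign = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def repeated_cv(X, y, model_factory, folds: int = 5, repeats: int = 10,
                seed: int = 0, positive=None,
                pca_components: int | None = None,
                pca_variance: float | None = None) -> CVResult:
    """Repeated stratified k-fold cross-validation.

    ``model_factory(seed)`` must return a fresh unfitted estimator.  When
    ``pca_components`` or ``pca_variance`` is given, PCA is fit on each
    training fold and applied to its test fold (fold-local, leakage-safe).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class ({counts.min()}) cannot be stratified into "
            f"{folds} folds")
    if positive is None:
        positive = classes[-1]
    master = np.random.SeedSequence(seed)
    repeat_seeds = [int(s % (2**31 - 1)) for s in master.generate_state(repeats)]
    records: list[dict] = []
    assignments = np.empty((repeats, len(y)), dtype=int)
    for r, rseed in enumerate(repeat_seeds):
        rng = np.random.default_rng(rseed)
        assign = _stratified_folds(y, folds, rng)
        assignments[r] = assign
        for f in range(folds):
            test = assign == f
            Xtr, ytr, Xte, yte = X[~test], y[~test], X[test], y[test]
            if pca_components is not None or pca_variance is not None:
                model_pca = pca_fit(
                    Xtr, n_components=pca_components,
                    variance_fraction=pca_variance if pca_variance else 0.95)
                Xtr = pca_transform(model_pca, Xtr)
                Xte = pca_transform(model_pca, Xte)
            est = model_factory(int(rng.integers(2**31 - 1)))
            est.fit(Xtr, ytr)
            pred = est.predict(Xte)
            cc = ConfusionCounts.from_predictions(yte, pred, positive)
            acc, prec, sens = classification_metrics(cc)
            pos_col = int(np.searchsorted(est.classes_, positive))
            scores = est.predict_proba(Xte)[:, pos_col]
            records.append({
                "repeat": r, "fold": f, "acc": acc, "precision": prec,
                "sensitivity": sens, "auc": auc(scores, yte, positive),
            })
    return CVResult(records=records, fold_assignments=assignments,
                    seeds=repeat_seeds, folds=folds, repeats=repeats)


# --------------------------------------------------------------------------
# One-way ANOVA

@dataclass(frozen=True)
class AnovaTable:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    f: float
    p: float


def anova_oneway(groups: list) -> AnovaTable:
    """Standard one-way ANOVA decomposition over >= 2 groups.

    Null hypothesis: all group means are equal.  Identical groups give
    F = 0, p = 1 (zero between-group sum of squares).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = float(sum(np.sum((a - a.mean()) ** 2) for a in arrays))
    ss_total = ss_between + ss_within
    df_between = len(arrays) - 1
    df_within = len(all_vals) - len(arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    if ms_within > 0:
        f = ms_between / ms_within
        p = float(stats.f.sf(f, df_between, df_within))
    elif ms_between > 0:
        f, p = float("inf"), 0.0
    else:
        f, p = 0.0, 1.0
    return AnovaTable(ss_between=ss_between, ss_within=ss_within,
                      ss_total=ss_total, df_between=df_between,
                      df_within=df_within, ms_between=ms_between,
                      ms_within=ms_within, f=float(f), p=float(p))
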