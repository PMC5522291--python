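"""Confusion bookkeeping, the Sn/Sp/Acc/MCC metric set, cross-validation, ROC.

Metrics are parameterized by misclassification counts: with N+ true sites of
which N-+ are missed, and N- false sites of which N+- are called positive,

    Sn  = 1 - N-+/N+
    Sp  = 1 - N+-/N-
    Acc = 1 - (N-+ + N+-)/(N+ + N-)
    MCC = (1 - (N-+/N+ + N+-/N-)) / sqrt((1 + (N+- - N-+)/N+)(1 + (N-+ - N+-)/N-))

which is algebraically the Matthews correlation coefficient on the usual
TP/FP/TN/FN counts.  The jackknife (leave-one-out) test is the normative
protocol: it yields a unique outcome for a fixed benchmark; stratified
k-fold is the cheaper subsampling alternative.  ROC scores are the pooled
out-of-fold vote fractions; AUC is the probability a random positive
outscores a random negative, ties counted one half.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import InputError
from .forest import ForestConfig, VoteForestClassifier


@dataclass(frozen=True)
class ConfusionCounts:
    """Class sizes and misclassification counts of a binary test."""

    n_pos: int
    n_neg: int
    fn: int  # true sites predicted negative (N-+)
    fp: int  # false sites predicted positive (N+-)

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise InputError("class sizes must be non-negative")
        if not 0 <= self.fn <= self.n_pos:
            raise InputError(f"fn={self.fn} outside [0, n_pos={self.n_pos}]")
        if not 0 <= self.fp <= self.n_neg:
            raise InputError(f"fp={self.fp} outside [0, n_neg={self.n_neg}]")

    @property
    def tp(self) -> int:
        return self.n_pos - self.fn

    @property
    def tn(self) -> int:
        return self.n_neg - self.fp


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity, specificity, accuracy and MCC with their source counts."""

    sn: float
    sp: float
    acc: float
    mcc: float
    counts: ConfusionCounts
    auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "n_pos": self.counts.n_pos,
            "n_neg": self.counts.n_neg,
            "fn": self.counts.fn,
            "fp": self.counts.fp,
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


@dataclass(frozen=True)
class RocCurve:
    """ROC points (FPR, TPR) from (0,0) to (1,1) and the area under them."""

    points: tuple[tuple[float, float], ...]
    auc: float


def metrics_from_counts(counts: ConfusionCounts) -> MetricsReport:
    """Compute Sn/Sp/Acc/MCC from confusion counts.

    When the MCC denominator vanishes (all predictions in one class, or a
    degenerate count pattern), MCC is defined as 0 and a warning is issued.
    """
    if counts.n_pos < 1 or counts.n_neg < 1:
        raise InputError("metrics need at least one sample in each class")
    n_pos, n_neg, fn, fp = counts.n_pos, counts.n_neg, counts.fn, counts.fp
    sn = 1.0 - fn / n_pos
    sp = 1.0 - fp / n_neg
    acc = 1.0 - (fn + fp) / (n_pos + n_neg)
    denom = (1.0 + (fp - fn) / n_pos) * (1.0 + (fn - fp) / n_neg)
    if denom <= 0.0 or math.isclose(denom, 0.0, abs_tol=1e-15):
        warnings.warn("MCC denominator is zero; reporting MCC=0", RuntimeWarning, stacklevel=2)
        mcc = 0.0
    else:
        mcc = (1.0 - (fn / n_pos + fp / n_neg)) / math.sqrt(denom)
    return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=mcc, counts=counts)


def counts_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Tally confusion counts from aligned binary label vectors (1 = positive)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise InputError("empty prediction vectors")
    if y_true.shape != y_pred.shape:
        raise InputError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    values = set(np.unique(y_true)) | set(np.unique(y_pred))
    if not values <= {0, 1}:
        raise InputError(f"labels must be binary 0/1, got {sorted(values)}")
    pos = y_true == 1
    return ConfusionCounts(
        n_pos=int(pos.sum()),
        n_neg=int((~pos).sum()),
        fn=int((pos & (y_pred == 0)).sum()),
        fp=int((~pos & (y_pred == 1)).sum()),
    )


def _fold_config(config: ForestConfig, fold: int) -> ForestConfig:
    """Per-fold seed derived from the master seed, so folds differ but reproduce."""
    return ForestConfig(
        n_trees=config.n_trees,
        subspace_dim=config.subspace_dim,
        seed=config.seed + fold,
        bootstrap=config.bootstrap,
        subspace_mode=config.subspace_mode,
    )


def jackknife(
    X, y, config: ForestConfig | None = None, threshold: float = 0.5
) -> tuple[np.ndarray, MetricsReport]:
    """Leave-one-out test: each sample scored by a forest trained on the rest.

    Returns the N out-of-fold vote fractions and the pooled metrics (with
    AUC over the pooled scores).  Fold i uses seed ``config.seed + i``.
    """
    config = config or ForestConfig()
    X = np.asarray(X)
    y = np.asarray(y)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise InputError("jackknife needs at least two samples per class")
    n = X.shape[0]
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        est = VoteForestClassifier.from_config(_fold_config(config, i)).fit(X[mask], y[mask])
        scores[i] = est.predict_proba(X[i : i + 1])[0, 1]
    preds = (scores >= threshold).astype(int)
    counts = counts_from_predictions(y, preds)
    report = metrics_from_counts(counts)
    return scores, MetricsReport(
        sn=report.sn, sp=report.sp, acc=report.acc, mcc=report.mcc,
        counts=counts, auc=roc_auc(y, scores).auc,
    )


def kfold(
    X,
    y,
    k: int,
    config: ForestConfig | None = None,
    seed: int | None = None,
    threshold: float = 0.5,
) -> tuple[np.ndarray, MetricsReport]:
    """Stratified k-fold test with pooled out-of-fold scores and metrics.

    The fold split is shuffled with ``seed`` (defaults to ``config.seed``);
    fold f trains with seed ``config.seed + f``.  ``k == N`` degenerates to
    the jackknife and delegates to it.
    """
    config = config or ForestConfig()
    X = np.asarray(X)
    y = np.asarray(y)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise InputError(f"k={k} outside [2, {n}]")
    if k == n:
        return jackknife(X, y, config, threshold)
    seed = config.seed if seed is None else seed
    scores = np.empty(n)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        est = VoteForestClassifier.from_config(_fold_config(config, f)).fit(
            X[train_idx], y[train_idx]
        )
        scores[test_idx] = est.predict_proba(X[test_idx])[:, 1]
    preds = (scores >= threshold).astype(int)
    counts = counts_from_predictions(y, preds)
    report = metrics_from_counts(counts)
    return scores, MetricsReport(
        sn=report.sn, sp=report.sp, acc=report.acc, mcc=report.mcc,
        counts=counts, auc=roc_auc(y, scores).auc,
    )


def roc_auc(y_true, scores) -> RocCurve:
    """ROC curve over all score thresholds and its area.

    AUC equals the rank statistic (probability a random positive outscores a
    random negative, ties counted 1/2); the curve points are monotone from
    (0,0) to (1,1).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise InputError("y_true and scores must align")
    if not np.all(np.isfinite(scores)):
        raise InputError("scores must be finite")
    if np.unique(y_true).size < 2:
        raise InputError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y_true, scores)
    return RocCurve(
        points=tuple(zip(fpr.tolist(), tpr.tolist())),
        auc=float(roc_auc_score(y_true, scores)),
    )
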