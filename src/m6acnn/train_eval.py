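"""k-fold cross-validation protocol and the evaluation metric suite.

The protocol is the 8/1/1 rotation: records are shuffled and split into k
(default 10) folds; in repetition t, fold t is the test set, fold
(t+1) mod k the validation set (used for checkpointing / early stopping),
and the remaining k-2 folds the training set. Per-repetition metrics are
computed on the test fold only and their arithmetic mean over the k
repetitions is reported. ROC/AUC is additionally computed on the pooled
out-of-fold test scores.

Metrics: ACC = (TP+TN)/(TP+TN+FP+FN), Sn = TP/(TP+FN), Sp = TN/(TN+FP),
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with MCC
defined as 0 when the denominator vanishes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .architecture import ModelSpec, TrainingConfig, build_model
from .io_encoding import LabeledDataset


@dataclass(frozen=True)
class FoldAssignment:
    """Maps each record index to a fold in [0, k)."""

    fold_of: np.ndarray  # shape (n,), int
    k: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def split(self, t: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Rotation t: (train, validation, test) index arrays.

        test = fold t, validation = fold (t+1) mod k, train = the rest.
        """
        test_fold = t % self.k
        val_fold = (t + 1) % self.k
        test = self.fold_indices(test_fold)
        val = self.fold_indices(val_fold)
        train = np.flatnonzero(
            (self.fold_of != test_fold) & (self.fold_of != val_fold)
        )
        return train, val, test


def make_folds(
    labels: np.ndarray | LabeledDataset,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> FoldAssignment:
    """Shuffle records into k folds whose sizes differ by at most one.

    Stratified mode (default) additionally balances per-fold class counts
    to within one record, while still keeping total fold sizes within one
    of each other (remainders of the two classes are dealt to disjoint
    folds where possible).
    """
    if isinstance(labels, LabeledDataset):
        labels = labels.labels
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=np.int64)
    if not stratified:
        perm = rng.permutation(n)
        for pos, idx in enumerate(perm):
            fold_of[idx] = pos % k
        return FoldAssignment(fold_of=fold_of, k=k)
    # Deal each class round-robin, continuing the deal across classes so
    # per-class remainders land on different folds and totals stay within 1.
    next_fold = 0
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        rng.shuffle(members)
        for idx in members:
            fold_of[idx] = next_fold
            next_fold = (next_fold + 1) % k
    return FoldAssignment(fold_of=fold_of, k=k)


@dataclass(frozen=True)
class ConfusionMatrix:
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


@dataclass(frozen=True)
class MetricSet:
    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float | None = None


def confusion_from_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> ConfusionMatrix:
    """Tally TP/TN/FP/FN with 'score >= threshold' called positive."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if scores.size and (scores.min() < 0.0 or scores.max() > 1.0):
        raise ValueError("scores must lie in [0, 1]")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """ACC, Sn, Sp, MCC from a confusion matrix (AUC left unset)."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics for an empty confusion matrix")
    tp, tn, fp, fn = (float(v) for v in (cm.tp, cm.tn, cm.fp, cm.fn))
    acc = (tp + tn) / (tp + tn + fp + fn)
    sn = tp / (tp + fn) if tp + fn > 0 else 0.0
    sp = tn / (tn + fp) if tn + fp > 0 else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return MetricSet(acc=acc, sn=sn, sp=sp, mcc=mcc)


def roc_curve(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points from sweeping the threshold over distinct scores.

    Tied scores are grouped, so trapezoidal integration of this curve gives
    ties half credit (the Mann-Whitney convention).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = (labels[order] == 1).astype(np.float64)
    tp_cum = np.cumsum(sorted_pos)
    fp_cum = np.cumsum(1.0 - sorted_pos)
    # keep only the last index within each tied-score block
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp_cum[distinct] / n_pos]
    fpr = np.r_[0.0, fp_cum[distinct] / n_neg]
    return fpr, tpr


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC (equals concordance probability)."""
    fpr, tpr = roc_curve(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def train_fold(
    spec: ModelSpec,
    config: TrainingConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
):
    """Train one model; returns (best-checkpoint model, training history)."""
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("empty train or validation set")
    model = build_model(spec, config)
    history = model.fit(X_train, y_train, X_val, y_val)
    return model, history


@dataclass
class CvResult:
    """Per-fold and aggregated cross-validation record."""

    fold_metrics: list[MetricSet]
    fold_confusions: list[ConfusionMatrix]
    mean: MetricSet
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    pooled_auc: float
    fold_histories: list[dict] = field(default_factory=list)
    seed: int = 0
    k: int = 10

    def per_fold_table(self) -> list[dict]:
        rows = []
        for i, m in enumerate(self.fold_metrics):
            rows.append(
                {"fold": i, "sp": m.sp, "sn": m.sn, "acc": m.acc, "mcc": m.mcc, "auc": m.auc}
            )
        rows.append(
            {
                "fold": "mean",
                "sp": self.mean.sp,
                "sn": self.mean.sn,
                "acc": self.mean.acc,
                "mcc": self.mean.mcc,
                "auc": self.mean.auc,
            }
        )
        return rows


def _mean_metrics(metrics: Sequence[MetricSet]) -> MetricSet:
    aucs = [m.auc for m in metrics if m.auc is not None]
    return MetricSet(
        acc=float(np.mean([m.acc for m in metrics])),
        sn=float(np.mean([m.sn for m in metrics])),
        sp=float(np.mean([m.sp for m in metrics])),
        mcc=float(np.mean([m.mcc for m in metrics])),
        auc=float(np.mean(aucs)) if aucs else None,
    )


def cross_validate(
    dataset: LabeledDataset,
    spec: ModelSpec,
    config: TrainingConfig,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
    threshold: float = 0.5,
) -> CvResult:
    """Run the full k-repetition rotation protocol.

    Each repetition trains a fresh model (fold-specific seed derived from
    ``seed``) on the k-2 training folds, early-stops on the validation
    fold, and scores the held-out test fold. Every record is scored as a
    test example exactly once; the pooled scores give the pooled AUC.
    """
    X, y = dataset.encode()
    folds = make_folds(y, k=k, seed=seed, stratified=stratified)
    fold_metrics: list[MetricSet] = []
    fold_confusions: list[ConfusionMatrix] = []
    fold_histories: list[dict] = []
    pooled_scores = np.empty(len(y))
    pooled_mask = np.zeros(len(y), dtype=bool)
    for t in range(k):
        train_idx, val_idx, test_idx = folds.split(t)
        fold_config = TrainingConfig(
            learning_rate=config.learning_rate,
            momentum=config.momentum,
            epochs=config.epochs,
            batch_size=config.batch_size,
            early_stop_patience=config.early_stop_patience,
            monitor=config.monitor,
            seed=config.seed + t,
        )
        model, history = train_fold(
            spec, fold_config, X[train_idx], y[train_idx], X[val_idx], y[val_idx]
        )
        scores = model.predict_proba(X[test_idx])
        pooled_scores[test_idx] = scores
        pooled_mask[test_idx] = True
        cm = confusion_from_scores(scores, y[test_idx], threshold=threshold)
        metrics = compute_metrics(cm)
        try:
            _, _, fold_auc = roc_auc(scores, y[test_idx])
        except ValueError:
            fold_auc = None
        fold_metrics.append(
            MetricSet(acc=metrics.acc, sn=metrics.sn, sp=metrics.sp, mcc=metrics.mcc, auc=fold_auc)
        )
        fold_confusions.append(cm)
        fold_histories.append(history)
    assert pooled_mask.all(), "rotation must test every record exactly once"
    _, _, pooled_auc = roc_auc(pooled_scores, y)
    return CvResult(
        fold_metrics=fold_metrics,
        fold_confusions=fold_confusions,
        mean=_mean_metrics(fold_metrics),
        pooled_scores=pooled_scores,
        pooled_labels=y,
        pooled_auc=pooled_auc,
        fold_histories=fold_histories,
        seed=seed,
        k=k,
    )
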