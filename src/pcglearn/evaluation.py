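"""Accuracy, stratified hold-out split and k-fold cross-validation.

Accuracy is ``100 x trace(confusion) / n`` — for the multi-class case this
equals the one-vs-rest micro-average of (TP + TN) / (TP + TN + FP + FN).
Splits and folds are stratified so the smallest class cannot vanish from
a fold; cross-validation aggregates per-fold metrics weighted by fold
size (the plain mean when folds are equal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvalReport",
    "CVReport",
    "accuracy",
    "confusion_matrix",
    "evaluate_predictions",
    "split_train_test",
    "stratified_folds",
    "kfold_cv",
]


@dataclass
class EvalReport:
    """Evaluation result on one sample set."""

    confusion: np.ndarray  # rows = true class, columns = predicted
    loss: float = float("nan")

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    @property
    def accuracy_pct(self) -> float:
        return accuracy(self.confusion)

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": round(self.accuracy_pct, 1),
            "loss": self.loss,
            "n": self.n,
            "confusion": self.confusion.tolist(),
        }


@dataclass
class CVReport:
    """k-fold cross-validation result."""

    k: int
    per_fold: list[EvalReport] = field(default_factory=list)

    @property
    def fold_sizes(self) -> np.ndarray:
        return np.array([r.n for r in self.per_fold])

    @property
    def weighted_accuracy_pct(self) -> float:
        sizes = self.fold_sizes
        accs = np.array([r.accuracy_pct for r in self.per_fold])
        return float(np.sum(sizes * accs) / np.sum(sizes))

    @property
    def weighted_loss(self) -> float:
        sizes = self.fold_sizes
        losses = np.array([r.loss for r in self.per_fold])
        return float(np.sum(sizes * losses) / np.sum(sizes))

    @property
    def pooled_confusion(self) -> np.ndarray:
        return np.sum([r.confusion for r in self.per_fold], axis=0)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weighted_accuracy_pct": round(self.weighted_accuracy_pct, 2),
            "weighted_loss": self.weighted_loss,
            "per_fold": [r.to_dict() for r in self.per_fold],
        }


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 3
) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (y_true, y_pred), 1)
    return mat


def accuracy(confusion: np.ndarray) -> float:
    """Percent of correct predictions: ``100 x trace / n``."""
    confusion = np.asarray(confusion)
    n = confusion.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    if (confusion < 0).any():
        raise ValueError("confusion counts must be non-negative")
    return float(100.0 * np.trace(confusion) / n)


def evaluate_predictions(
    y_true, y_pred, *, loss: float = float("nan"), n_classes: int = 3
) -> EvalReport:
    return EvalReport(confusion_matrix(y_true, y_pred, n_classes), loss=loss)


def _stratified_assignment(
    labels: np.ndarray, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Assign each sample to a group, class by class, with per-class group
    sizes proportional to ``weights`` (largest-remainder rounding) and a
    shuffled order.  Returns the group index per sample."""
    labels = np.asarray(labels, dtype=np.int64)
    out = np.empty(len(labels), dtype=np.int64)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        quota = weights * len(idx)
        counts = np.floor(quota).astype(int)
        remainder = quota - counts
        for g in np.argsort(-remainder)[: len(idx) - counts.sum()]:
            counts[g] += 1
        groups = np.repeat(np.arange(len(weights)), counts)
        out[idx] = groups
    return out


def split_train_test(
    labels: np.ndarray, ratio: float = 0.70, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split; returns (train indices, test indices).

    Disjoint, covering every sample, reproducible per seed; per-class
    train proportions match ``ratio`` within rounding.  Falls back to an
    unstratified split (with a warning) if some class has < 2 members.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    labels = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(seed)
    counts = np.bincount(labels)
    if (counts[counts > 0] < 2).any():
        import warnings

        warnings.warn(
            "a class has fewer than 2 members; falling back to an "
            "unstratified split",
            stacklevel=2,
        )
        idx = rng.permutation(len(labels))
        cut = int(round(ratio * len(labels)))
        return np.sort(idx[:cut]), np.sort(idx[cut:])
    groups = _stratified_assignment(labels, np.array([ratio, 1.0 - ratio]), rng)
    return np.flatnonzero(groups == 0), np.flatnonzero(groups == 1)


def stratified_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index (0..k-1) per sample; stratified, near-equal sizes
    (per-class fold sizes differ by at most 1)."""
    labels = np.asarray(labels, dtype=np.int64)
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the number of samples {len(labels)}")
    rng = np.random.default_rng(seed)
    return _stratified_assignment(labels, np.full(k, 1.0 / k), rng)


def kfold_cv(
    X: np.ndarray,
    labels: np.ndarray,
    model_factory,
    train_cfg,
    *,
    k: int = 5,
    seed: int = 0,
    verbose: bool = False,
) -> CVReport:
    """Stratified k-fold cross-validation.

    ``model_factory(fold_index)`` must return a fresh untrained model with
    the shared fit/predict interface.  Each sample is tested exactly once;
    the report aggregates fold metrics weighted by fold size.
    """
    labels = np.asarray(labels, dtype=np.int64)
    folds = stratified_folds(labels, k=k, seed=seed)
    report = CVReport(k=k)
    for fold in range(k):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        model = model_factory(fold)
        model.fit(X[train_idx], labels[train_idx], train_cfg)
        pred = model.predict(X[test_idx])
        loss = model.evaluate_loss(X[test_idx], labels[test_idx])
        report.per_fold.append(
            evaluate_predictions(labels[test_idx], pred, loss=loss)
        )
        if verbose:
            r = report.per_fold[-1]
            print(f"  fold {fold + 1}/{k}: accuracy {r.accuracy_pct:.1f}% "
                  f"(n={r.n})")
    return report
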