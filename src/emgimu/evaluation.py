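"""Repetition-wise cross-validation, rest balancing and accuracy metrics.

Fold ``j`` of the cross-validation holds out repetition ``j`` of every class
(together with the rest windows that inherit that repetition index), so
train and test windows never come from the same trial. Test folds are
optionally rebalanced by discarding rest windows far from muscle activity,
preventing the over-represented rest class from inflating accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from emgimu.classification import LDAModel, fit_lda, predict
from emgimu.errors import ValidationError
from emgimu.features import FeatureMatrix, apply_standardizer, fit_standardizer

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    """Repetition-wise cross-validation: ``k`` folds, one per repetition."""

    k: int = 6

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError("CVConfig: k must be >= 2")


@dataclass
class EvalResult:
    fold_ca: np.ndarray  # per-fold CA in percent
    confusion: np.ndarray  # pooled, row-normalized (C x C)
    classes: np.ndarray
    retained_counts: list[int] = field(default_factory=list)

    @property
    def mean_ca(self) -> float:
        return float(np.mean(self.fold_ca))


def repetition_folds(
    F: FeatureMatrix, cfg: CVConfig = CVConfig()
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition rows into ``k`` (train, test) splits by repetition index.

    Test fold ``j`` consists of every window whose repetition index equals
    ``j`` (non-rest windows of repetition ``j`` of every class, plus the
    rest windows that inherit it). Folds are disjoint and exhaustive.
    """
    reps = F.repetition
    for c in np.unique(F.y):
        if c == 0:
            continue
        n_reps = np.unique(reps[F.y == c]).size
        if n_reps < cfg.k:
            raise ValidationError(
                f"class {c} has {n_reps} repetitions, fewer than k={cfg.k}"
            )
    folds = []
    all_rows = np.arange(F.n_windows)
    for j in range(1, cfg.k + 1):
        test = all_rows[reps == j]
        train = all_rows[reps != j]
        if test.size == 0:
            raise ValidationError(f"repetition {j} holds no windows")
        folds.append((train, test))
    return folds


def balance_rest(F: FeatureMatrix, rows: np.ndarray, target: str = "mean") -> np.ndarray:
    """Down-sample rest windows by temporal distance to muscle activity.

    Among ``rows``, rest windows are ranked by their temporal distance (in
    seconds, window end-time to window end-time) to the nearest non-rest
    window; the nearest are retained until the rest count equals the rounded
    mean per-class count of the non-rest classes. Distance ties retain the
    earlier window. All non-rest rows are kept and row order is preserved.
    """
    rows = np.asarray(rows)
    y = F.y[rows]
    t = F.t[rows]
    rest_mask = y == 0
    if not rest_mask.any():
        log.warning("balance_rest: no rest windows; input returned unchanged")
        return rows
    active_classes = np.unique(y[~rest_mask])
    if active_classes.size == 0:
        raise ValidationError("balance_rest: rows contain no non-rest class")

    if target != "mean":
        raise ValidationError(f"unknown balancing rule {target!r}")
    quota = int(round(np.mean([np.sum(y == c) for c in active_classes])))

    t_active = t[~rest_mask]
    rest_idx = np.flatnonzero(rest_mask)
    dist = np.min(np.abs(t[rest_idx][:, None] - t_active[None, :]), axis=1)
    # Stable sort on distance keeps earlier windows first among ties.
    order = np.argsort(dist, kind="stable")
    keep_rest = set(rest_idx[order[:quota]].tolist())

    keep_mask = ~rest_mask
    keep_local = np.flatnonzero(
        keep_mask | np.isin(np.arange(rows.size), list(keep_rest))
    )
    return rows[keep_local]


def classification_accuracy(pred: np.ndarray, true: np.ndarray) -> float:
    """Percent of correctly classified instances."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape or pred.size == 0:
        raise ValidationError("classification_accuracy: need equal-length non-empty inputs")
    return 100.0 * float(np.mean(pred == true))


def confusion(
    pred: np.ndarray, true: np.ndarray, class_map: dict[int, str]
) -> np.ndarray:
    """Row-normalized confusion matrix over the classes of ``class_map``.

    Entry ``(i, j)`` is the fraction of true-class-``i`` windows predicted as
    class ``j``; rows with no true instances are all zero.
    """
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape or pred.size == 0:
        raise ValidationError("confusion: need equal-length non-empty inputs")
    classes = np.array(sorted(class_map))
    unknown = (set(np.unique(pred)) | set(np.unique(true))) - set(classes.tolist())
    if unknown:
        raise ValidationError(f"confusion: labels outside class_map: {sorted(unknown)}")
    index = {c: i for i, c in enumerate(classes.tolist())}
    C = classes.size
    M = np.zeros((C, C))
    for p, tr in zip(pred, true):
        M[index[int(tr)], index[int(p)]] += 1
    sums = M.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(sums > 0, M / np.where(sums > 0, sums, 1), 0.0)
    return M


def crossval_evaluate(
    F: FeatureMatrix,
    cv: CVConfig = CVConfig(),
    shrinkage: float = 1e-3,
    balance: bool = True,
) -> EvalResult:
    """Full repetition-wise cross-validated evaluation.

    Per fold: the standardizer and the classifier are fitted on training
    rows only; the test fold is optionally rest-balanced; CA is recorded per
    fold and raw prediction counts are pooled into one confusion matrix.
    """
    folds = repetition_folds(F, cv)
    classes = np.array(sorted(F.class_map)) if F.class_map else np.unique(F.y)
    index = {c: i for i, c in enumerate(classes.tolist())}
    C = classes.size
    counts = np.zeros((C, C))
    cas = []
    retained = []
    for train, test in folds:
        S = fit_standardizer(F, train)
        Fz = apply_standardizer(S, F)
        model = fit_lda(Fz.X[train], Fz.y[train], shrinkage=shrinkage)
        test_rows = balance_rest(F, test) if balance else test
        retained.append(int(test_rows.size))
        pred = predict(model, Fz.X[test_rows])
        true = Fz.y[test_rows]
        cas.append(classification_accuracy(pred, true))
        for p, tr in zip(np.atleast_1d(pred), true):
            counts[index[int(tr)], index[int(p)]] += 1
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        conf = np.where(sums > 0, counts / np.where(sums > 0, sums, 1), 0.0)
    return EvalResult(
        fold_ca=np.asarray(cas),
        confusion=conf,
        classes=classes,
        retained_counts=retained,
    )


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 100,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("bootstrap_ci: need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
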