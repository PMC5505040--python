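"""Shared-covariance Gaussian classifier with posterior-threshold rejection.

The model is the class-conditional Gaussian with a covariance matrix pooled
across classes (linear decision boundaries). Posteriors are computed in the
log domain through a Cholesky factorization, so no under/overflow occurs for
standardized features. ``NO_DECISION`` (-1) is a first-class output of the
rejection rule, consumed downstream as "hold state".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from emgimu.errors import ValidationError

#: Sentinel emitted when no class posterior clears the rejection threshold.
NO_DECISION: int = -1


@dataclass(frozen=True)
class RejectionConfig:
    """Posterior confidence threshold (strict inequality)."""

    theta: float = 0.995

    def __post_init__(self) -> None:
        if not 0 < self.theta <= 1:
            raise ValidationError("RejectionConfig: theta must be in (0, 1]")


@dataclass
class LDAModel:
    """Fitted shared-covariance Gaussian model.

    ``shared_covariance`` is the pooled within-class covariance after
    shrinkage toward its own diagonal: ``(1 - lam) * S + lam * diag(S)``.
    """

    class_means: np.ndarray  # (C, d)
    shared_covariance: np.ndarray  # (d, d)
    priors: np.ndarray  # (C,)
    shrinkage: float
    classes: np.ndarray  # (C,) class ids, sorted

    def __post_init__(self) -> None:
        self._cho = cho_factor(self.shared_covariance, lower=True)

    @property
    def n_classes(self) -> int:
        return self.classes.shape[0]

    @property
    def d(self) -> int:
        return self.class_means.shape[1]


def fit_lda(X: np.ndarray, y: np.ndarray, shrinkage: float = 1e-3) -> LDAModel:
    """Fit class means, pooled within-class covariance and empirical priors.

    The pooled covariance uses the unbiased ``n - C`` denominator and is
    shrunk as ``(1 - lam) * S + lam * diag(S)``; with limited training
    windows and up to 192 features the raw pooled matrix is frequently
    ill-conditioned, hence the small default shrinkage.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("fit_lda: X must be (n, d) with matching y")
    if not 0 <= shrinkage <= 1:
        raise ValidationError("fit_lda: shrinkage must be in [0, 1]")
    classes = np.unique(y)
    if classes.shape[0] < 2:
        raise ValidationError("fit_lda: need at least 2 classes")
    n, d = X.shape
    C = classes.shape[0]

    means = np.empty((C, d))
    priors = np.empty(C)
    scatter = np.zeros((d, d))
    for i, c in enumerate(classes):
        rows = X[y == c]
        if rows.shape[0] < 2:
            raise ValidationError(f"fit_lda: class {c} has fewer than 2 rows")
        means[i] = rows.mean(axis=0)
        priors[i] = rows.shape[0] / n
        centered = rows - means[i]
        scatter += centered.T @ centered
    cov = scatter / (n - C)
    cov = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))

    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= evals[-1] * 1e-10:
        raise ValidationError(
            "fit_lda: pooled covariance is singular or near-singular; "
            "increase shrinkage above 0"
        )
    return LDAModel(
        class_means=means,
        shared_covariance=cov,
        priors=priors,
        shrinkage=shrinkage,
        classes=classes,
    )


def _log_scores(m: LDAModel, X: np.ndarray) -> np.ndarray:
    """Unnormalized log posteriors ``log prior_c - 0.5 (x-mu_c)' S^{-1}
    (x-mu_c)`` for each row; the shared log-determinant cancels."""
    scores = np.empty((X.shape[0], m.n_classes))
    for i in range(m.n_classes):
        diff = X - m.class_means[i]
        sol = cho_solve(m._cho, diff.T)
        scores[:, i] = np.log(m.priors[i]) - 0.5 * np.einsum("ij,ji->i", diff, sol)
    return scores


def predict_posterior(m: LDAModel, x: np.ndarray) -> np.ndarray:
    """Posterior class probabilities for one vector or a batch of rows.

    Computed via log-sum-exp normalization; rows sum to 1 to within
    floating-point rounding.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != m.d:
        raise ValidationError(
            f"predict_posterior: expected {m.d} features, got {X.shape[1]}"
        )
    scores = _log_scores(m, X)
    scores -= scores.max(axis=1, keepdims=True)
    p = np.exp(scores)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if single else p


def predict(m: LDAModel, x: np.ndarray) -> np.ndarray | int:
    """Maximum-posterior class id(s)."""
    p = predict_posterior(m, x)
    if p.ndim == 1:
        return int(m.classes[int(np.argmax(p))])
    return m.classes[np.argmax(p, axis=1)]


def predict_with_rejection(
    m: LDAModel, x: np.ndarray, rc: RejectionConfig = RejectionConfig()
) -> int | np.ndarray:
    """Argmax class iff the maximum posterior strictly exceeds ``theta``,
    else :data:`NO_DECISION`.

    Posterior ties are broken toward the lower class id (argmax takes the
    first maximum; a measure-zero event for continuous inputs).
    """
    p = predict_posterior(m, x)
    single = p.ndim == 1
    P = np.atleast_2d(p)
    best = np.argmax(P, axis=1)
    out = np.where(
        P[np.arange(P.shape[0]), best] > rc.theta, m.classes[best], NO_DECISION
    ).astype(int)
    return int(out[0]) if single else out
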