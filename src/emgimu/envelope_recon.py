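"""EMG-envelope reconstruction from same-sensor inertial channels.

For each sensor, the window-level MAV series (the EMG envelope) is regressed
on the window means of one tri-axial IM modality (accelerometer, gyroscope
or magnetometer) from the same sensor, by ordinary least squares with an
intercept. The headline score is the held-out variance accounted for (VAF)
under repetition-wise k-fold cross-validation; the training VAF is reported
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from emgimu.dataio import Recording
from emgimu.errors import ValidationError
from emgimu.features import FeatureMatrix, WindowConfig, build_feature_matrix
from emgimu.preprocessing import synchronize

MODALITY_AXES = {"acc": (0, 1, 2), "gyro": (3, 4, 5), "mag": (6, 7, 8)}


@dataclass
class ReconstructionResult:
    sensor: int
    modality: str  # "acc" | "gyro" | "mag"
    coefficients: np.ndarray  # 3 weights
    intercept: float
    vaf: float  # held-out (cross-validated)
    vaf_train: float


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    A = np.column_stack([X, np.ones(X.shape[0])])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta[:-1], float(beta[-1])


def _vaf(y: np.ndarray, pred: np.ndarray) -> float:
    return 1.0 - float(np.var(y - pred) / np.var(y))


def fit_reconstruction(
    im_feats: np.ndarray,
    envelope: np.ndarray,
    k: int = 6,
    repetition: Optional[np.ndarray] = None,
    sensor: int = 0,
    modality: str = "acc",
) -> ReconstructionResult:
    """OLS reconstruction of an envelope series from 3 IM feature series.

    ``im_feats`` is (n, 3) and ``envelope`` (n,), aligned on the same window
    grid. Held-out VAF is estimated by k-fold cross-validation —
    repetition-wise when a per-window ``repetition`` index is supplied,
    otherwise over contiguous blocks. Held-out VAF may be negative; training
    VAF (OLS with intercept) is always >= 0.
    """
    X = np.asarray(im_feats, dtype=float)
    y = np.asarray(envelope, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] != y.shape[0]:
        raise ValidationError("fit_reconstruction: need aligned (n, 3) and (n,) series")
    n = y.shape[0]
    if n <= 4:
        raise ValidationError("fit_reconstruction: need more than 4 windows")
    if np.var(y) == 0:
        raise ValidationError("fit_reconstruction: constant envelope, VAF undefined")

    coef, intercept = _ols(X, y)
    vaf_train = _vaf(y, X @ coef + intercept)

    if repetition is not None:
        rep = np.asarray(repetition)
        fold_ids = np.unique(rep)[:k]
        folds = [np.flatnonzero(rep == r) for r in fold_ids]
    else:
        folds = [f for f in np.array_split(np.arange(n), k) if f.size]

    resid = np.zeros(n)
    scored = np.zeros(n, dtype=bool)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        if train.size < 4 or test.size == 0:
            continue
        c, b = _ols(X[train], y[train])
        resid[test] = y[test] - (X[test] @ c + b)
        scored[test] = True
    if not scored.any() or np.var(y[scored]) == 0:
        raise ValidationError("fit_reconstruction: cross-validation produced no folds")
    vaf_cv = 1.0 - float(np.var(resid[scored]) / np.var(y[scored]))

    return ReconstructionResult(
        sensor=sensor,
        modality=modality,
        coefficients=coef,
        intercept=intercept,
        vaf=vaf_cv,
        vaf_train=vaf_train,
    )


def reconstruction_suite(
    rec: Recording, wc: WindowConfig = WindowConfig(), k: int = 6
) -> list[ReconstructionResult]:
    """Fit every sensor x {acc, gyro, mag} reconstruction for a recording.

    Windows are pooled across all movements. Returns ``3 * n_sensors``
    results (36 for the standard 12-sensor layout).
    """
    ar = synchronize(rec)
    F = build_feature_matrix(ar, wc, modality="both")
    out: list[ReconstructionResult] = []
    for s in range(1, rec.n_sensors + 1):
        block = F.sensor_block(s)
        names = [F.columns[j].name for j in block]
        mav = F.X[:, block[names.index("MAV")]]
        im_cols = [j for j in block if F.columns[j].modality == "im"]
        for modality, axes in MODALITY_AXES.items():
            Xm = F.X[:, [im_cols[a] for a in axes]]
            out.append(
                fit_reconstruction(
                    Xm,
                    mav,
                    k=k,
                    repetition=F.repetition,
                    sensor=s,
                    modality=modality,
                )
            )
    return out
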