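"""Sliding-window segmentation and per-sensor feature extraction.

Each sensor contributes 16 features per window when both modalities are
used: 7 time-domain EMG features (MAV, WL, AR1..AR4, LogVar) and the 9 IM
channel means (MV). Windows are indexed on the EMG grid; IM features are
computed from the synchronized 2 kHz representation so both modalities share
exact window boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from emgimu.dataio import IM_SUFFIXES, N_IM_CHANNELS
from emgimu.errors import ValidationError
from emgimu.preprocessing import AlignedRecording

log = logging.getLogger(__name__)

#: Variance floor applied before the logarithm in LogVar.
LOGVAR_EPS = 1e-12

EMG_FEATURE_NAMES = ("MAV", "WL", "AR1", "AR2", "AR3", "AR4", "LogVar")
IM_FEATURE_NAMES = tuple(f"MV_{suf}" for suf in IM_SUFFIXES)


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window parameters (defaults: 256 ms length, 50 ms increment,
    i.e. 80% overlap)."""

    length_ms: float = 256.0
    increment_ms: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.increment_ms <= self.length_ms:
            raise ValidationError(
                "WindowConfig: need 0 < increment_ms <= length_ms"
            )

    def in_samples(self, f_hz: float) -> tuple[int, int]:
        return (
            int(round(self.length_ms * f_hz / 1000.0)),
            int(round(self.increment_ms * f_hz / 1000.0)),
        )


@dataclass(frozen=True)
class ColumnDesc:
    """Descriptor of one feature-matrix column."""

    sensor: int  # 1-based
    modality: str  # "emg" | "im"
    name: str

    def __str__(self) -> str:
        return f"s{self.sensor:02d}_{self.modality}_{self.name}"


@dataclass
class FeatureMatrix:
    """Windows x features design matrix with per-window metadata.

    ``columns`` maps every column to (sensor, modality, feature name), which
    lets downstream selection operate on whole per-sensor blocks. ``t`` holds
    window end-times in seconds; ``repetition`` is the per-class ordinal of
    the enclosing activity segment (rest windows inherit the repetition of
    the preceding segment).
    """

    X: np.ndarray
    y: np.ndarray
    t: np.ndarray
    columns: list[ColumnDesc]
    repetition: np.ndarray
    class_map: dict[int, str] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def sensors(self) -> list[int]:
        seen: list[int] = []
        for c in self.columns:
            if c.sensor not in seen:
                seen.append(c.sensor)
        return seen

    def sensor_block(self, sensor: int) -> np.ndarray:
        """Column indices belonging to one sensor (contiguous by
        construction)."""
        idx = [j for j, c in enumerate(self.columns) if c.sensor == sensor]
        if not idx:
            raise ValidationError(f"no columns for sensor {sensor}")
        return np.asarray(idx, dtype=int)

    def restrict(self, rows=None, cols=None) -> "FeatureMatrix":
        rows = np.arange(self.n_windows) if rows is None else np.asarray(rows)
        cols = np.arange(self.d) if cols is None else np.asarray(cols)
        return FeatureMatrix(
            X=self.X[np.ix_(rows, cols)],
            y=self.y[rows],
            t=self.t[rows],
            columns=[self.columns[j] for j in cols],
            repetition=self.repetition[rows],
            class_map=self.class_map,
        )


@dataclass
class Windows:
    """Window index bookkeeping produced by :func:`segment_windows`."""

    starts: np.ndarray  # EMG sample index of each window start
    length: int  # samples per window
    increment: int
    labels: np.ndarray  # majority label per window
    repetition: np.ndarray
    t_end: np.ndarray  # window end time (s)

    def __len__(self) -> int:
        return self.starts.shape[0]


def _per_sample_repetition(labels: np.ndarray) -> np.ndarray:
    """Per-class segment ordinal for every sample.

    Non-rest samples get the ordinal (1-based) of their segment among the
    segments of the same class. Rest samples inherit the ordinal of the
    preceding non-rest segment; leading rest gets 1.
    """
    n = labels.shape[0]
    rep = np.empty(n, dtype=int)
    counts: dict[int, int] = {}
    bounds = np.flatnonzero(np.diff(labels)) + 1
    edges = [0, *bounds.tolist(), n]
    last = 1
    for a, b in zip(edges[:-1], edges[1:]):
        c = int(labels[a])
        if c != 0:
            counts[c] = counts.get(c, 0) + 1
            last = counts[c]
        rep[a:b] = last
    return rep


def segment_windows(ar: AlignedRecording, cfg: WindowConfig = WindowConfig()) -> Windows:
    """Enumerate sliding windows on the EMG grid.

    Window ``k`` covers samples ``[k*inc, k*inc + len)``; the count is
    ``floor((n - len) / inc) + 1``. The window label is the majority label
    within the window, ties broken toward the label at the window's last
    sample.
    """
    length, inc = cfg.in_samples(ar.f_emg)
    n = ar.n_samples
    if n < length:
        raise ValidationError(
            f"recording has {n} samples, shorter than one {length}-sample window"
        )
    count = (n - length) // inc + 1
    starts = np.arange(count) * inc

    sample_rep = _per_sample_repetition(ar.labels)
    labels = np.empty(count, dtype=int)
    reps = np.empty(count, dtype=int)
    for k, s in enumerate(starts):
        win = ar.labels[s : s + length]
        vals, cnts = np.unique(win, return_counts=True)
        best = cnts.max()
        tied = vals[cnts == best]
        lab = int(win[-1]) if win[-1] in tied else int(tied[0])
        labels[k] = lab
        # Repetition: ordinal of the enclosing segment for the majority
        # class; rest windows inherit the preceding segment's ordinal.
        if lab != 0:
            pos = s + int(np.flatnonzero(win == lab)[-1])
        else:
            pos = s + length - 1
        reps[k] = sample_rep[pos]
    t_end = (starts + length) / ar.f_emg
    return Windows(
        starts=starts,
        length=length,
        increment=inc,
        labels=labels,
        repetition=reps,
        t_end=t_end,
    )


def burg_ar(x: np.ndarray, order: int = 4) -> np.ndarray:
    """Burg-method AR coefficient estimation, batched over rows.

    Fits the forward-prediction model ``x_t = sum_j a_j x_{t-j} + e_t`` to
    each (demeaned) row of ``x`` and returns the coefficients ``a_1..a_p``
    with shape ``(n_rows, order)``. Degenerate (flat) rows yield zeros.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    m, n = x.shape
    if n < order + 2:
        raise ValidationError(f"window length {n} too short for AR({order})")
    x = x - x.mean(axis=1, keepdims=True)

    # Error-filter polynomial a = [1, a1, ..., ak]; prediction coefficients
    # are the negated tail.
    a = np.zeros((m, order + 1))
    a[:, 0] = 1.0
    ef = x.copy()
    eb = x.copy()
    for k in range(order):
        efp = ef[:, 1:]
        ebp = eb[:, :-1]
        den = np.einsum("ij,ij->i", efp, efp) + np.einsum("ij,ij->i", ebp, ebp)
        num = -2.0 * np.einsum("ij,ij->i", efp, ebp)
        kref = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        ef = efp + kref[:, None] * ebp
        eb = ebp + kref[:, None] * efp
        a[:, : k + 2] = a[:, : k + 2] + kref[:, None] * a[:, : k + 2][:, ::-1]
    return -a[:, 1:]


def emg_td_features(window: np.ndarray, ar_order: int = 4) -> np.ndarray:
    """Time-domain EMG feature vector for a single window.

    Returns ``(MAV, WL, AR1..ARp, LogVar)``: mean absolute value, waveform
    length (sum of absolute successive differences), Burg AR prediction
    coefficients and the natural log of the unbiased sample variance
    (floored at ``LOGVAR_EPS``).
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1:
        raise ValidationError("emg_td_features expects a 1-D window")
    if x.shape[0] < ar_order + 2:
        raise ValidationError(
            f"window length {x.shape[0]} too short for AR({ar_order})"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("emg_td_features: non-finite samples")
    mav = float(np.mean(np.abs(x)))
    wl = float(np.sum(np.abs(np.diff(x))))
    ar = burg_ar(x[None, :], ar_order)[0]
    logvar = float(np.log(max(np.var(x, ddof=1), LOGVAR_EPS)))
    return np.concatenate(([mav, wl], ar, [logvar]))


def im_mean_features(window: np.ndarray) -> np.ndarray:
    """Per-channel arithmetic mean of a (samples x 9) IM window."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValidationError("im_mean_features: empty window")
    if w.ndim != 2:
        raise ValidationError("im_mean_features expects a 2-D (samples x channels) window")
    return w.mean(axis=0)


def _emg_features_batch(channel: np.ndarray, win: Windows, ar_order: int = 4) -> np.ndarray:
    """All 7 EMG features for every window of one channel, vectorized."""
    view = sliding_window_view(channel, win.length)[:: win.increment][: len(win)]
    mav = np.mean(np.abs(view), axis=1)
    wl = np.sum(np.abs(np.diff(view, axis=1)), axis=1)
    ar = burg_ar(view, ar_order)
    logvar = np.log(np.maximum(np.var(view, axis=1, ddof=1), LOGVAR_EPS))
    return np.column_stack([mav, wl, ar, logvar])


def build_feature_matrix(
    ar: AlignedRecording,
    cfg: WindowConfig = WindowConfig(),
    modality: str = "both",
    sensors: Optional[Sequence[int]] = None,
) -> FeatureMatrix:
    """Extract the windows x features design matrix.

    ``sensors`` is a 1-based subset of the layout (default: all). Column
    count is ``7*|sensors|`` for EMG only, ``9*|sensors|`` for IM only and
    ``16*|sensors|`` for both; per-sensor blocks are contiguous, EMG features
    before IM features within a block.
    """
    if modality not in ("emg", "im", "both"):
        raise ValidationError(f"unknown modality {modality!r}")
    all_sensors = list(range(1, ar.n_sensors + 1))
    if sensors is None:
        sensors = all_sensors
    sensors = list(sensors)
    if not sensors:
        raise ValidationError("sensors must be a non-empty subset")
    unknown = set(sensors) - set(all_sensors)
    if unknown:
        raise ValidationError(f"unknown sensor indices {sorted(unknown)}")

    win = segment_windows(ar, cfg)
    blocks: list[np.ndarray] = []
    columns: list[ColumnDesc] = []
    view_cache: dict[int, np.ndarray] = {}
    for s in sensors:
        if modality in ("emg", "both"):
            blocks.append(_emg_features_batch(ar.emg[:, s - 1], win))
            columns.extend(ColumnDesc(s, "emg", nm) for nm in EMG_FEATURE_NAMES)
        if modality in ("im", "both"):
            cols = slice((s - 1) * N_IM_CHANNELS, s * N_IM_CHANNELS)
            means = np.empty((len(win), N_IM_CHANNELS))
            for j in range(N_IM_CHANNELS):
                ch = ar.im_on_emg_grid[:, cols][:, j]
                view = sliding_window_view(ch, win.length)[:: win.increment][: len(win)]
                means[:, j] = view.mean(axis=1)
            blocks.append(means)
            columns.extend(ColumnDesc(s, "im", nm) for nm in IM_FEATURE_NAMES)

    X = np.column_stack(blocks)
    return FeatureMatrix(
        X=X,
        y=win.labels,
        t=win.t_end,
        columns=columns,
        repetition=win.repetition,
        class_map=dict(ar.class_map),
    )


@dataclass
class Standardizer:
    """Per-column training mean/sd; zero-variance columns are dropped."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # indices into the original column set

    @property
    def n_kept(self) -> int:
        return self.kept.shape[0]


def fit_standardizer(F: FeatureMatrix, train_rows: np.ndarray) -> Standardizer:
    """Estimate column means and sds on ``train_rows`` only.

    Columns whose training sd is zero are dropped with a logged warning
    (they carry no information and would divide by zero).
    """
    train_rows = np.asarray(train_rows)
    if train_rows.size == 0:
        raise ValidationError("fit_standardizer: empty training row set")
    Xt = F.X[train_rows]
    mean = Xt.mean(axis=0)
    sd = Xt.std(axis=0, ddof=0)
    kept = np.flatnonzero(sd > 0)
    if kept.size < F.d:
        dropped = [str(F.columns[j]) for j in np.flatnonzero(sd == 0)]
        log.warning("fit_standardizer: dropping zero-variance columns %s", dropped)
    if kept.size == 0:
        raise ValidationError("fit_standardizer: all training columns have zero variance")
    return Standardizer(mean=mean[kept], sd=sd[kept], kept=kept)


def apply_standardizer(S: Standardizer, F: FeatureMatrix) -> FeatureMatrix:
    """Transform ``F`` with training statistics (train or test rows alike)."""
    X = (F.X[:, S.kept] - S.mean) / S.sd
    return FeatureMatrix(
        X=X,
        y=F.y,
        t=F.t,
        columns=[F.columns[j] for j in S.kept],
        repetition=F.repetition,
        class_map=F.class_map,
    )
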