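"""Interference suppression, multi-rate synchronization, label refinement.

Order matters: EMG is Hampel-filtered first (IM channels are used raw), then
IM channels are linearly interpolated onto the EMG sample grid so that both
modalities share exact window boundaries downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from emgimu.dataio import Recording, SensorLayout
from emgimu.errors import ValidationError

log = logging.getLogger(__name__)

#: Consistency factor making the MAD an unbiased sd estimator under normality.
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class HampelConfig:
    half_window: int = 100
    n_sigmas: float = 3.0

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise ValidationError("HampelConfig: half_window must be >= 1")
        if self.n_sigmas <= 0:
            raise ValidationError("HampelConfig: n_sigmas must be > 0")


@dataclass
class AlignedRecording:
    """A recording after filtering and synchronization.

    ``im_on_emg_grid`` holds every IM channel linearly interpolated to the
    EMG sample grid, so both matrices have the same number of rows.
    """

    emg: np.ndarray
    im_on_emg_grid: np.ndarray
    labels: np.ndarray
    class_map: dict[int, str]
    layout: SensorLayout
    f_emg: float
    f_im: float
    meta: dict = field(default_factory=dict)

    @property
    def n_sensors(self) -> int:
        return self.layout.n_sensors

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]


# Cap scratch memory for the sliding-window median at ~40 MB per chunk.
_HAMPEL_CHUNK_FLOATS = 5_000_000


def hampel_filter(signal: np.ndarray, cfg: HampelConfig = HampelConfig()) -> np.ndarray:
    """Sliding-window Hampel outlier rejection.

    Sample ``i`` is replaced by its window median iff
    ``|x_i - median| > n_sigmas * 1.4826 * MAD`` of the window
    ``x[i-hw : i+hw+1]``. Edge windows are truncated symmetrically (radius
    ``min(i, hw, n-1-i)``). A window with MAD = 0 flags no outliers, so flat
    segments pass through unchanged.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValidationError("hampel_filter expects a 1-D signal")
    n = x.shape[0]
    hw = cfg.half_window
    if n <= 2 * hw:
        raise ValidationError(
            f"signal length {n} must exceed 2 * half_window = {2 * hw}"
        )
    out = x.copy()

    # Interior samples: full windows, processed in chunks to bound memory.
    width = 2 * hw + 1
    chunk = max(1, _HAMPEL_CHUNK_FLOATS // width)
    for s in range(hw, n - hw, chunk):
        e = min(n - hw, s + chunk)
        w = sliding_window_view(x[s - hw : e + hw], width)
        med = np.median(w, axis=1)
        mad = np.median(np.abs(w - med[:, None]), axis=1)
        dev = np.abs(x[s:e] - med)
        mask = (mad > 0) & (dev > cfg.n_sigmas * MAD_SCALE * mad)
        out[s:e][mask] = med[mask]

    # Edges: symmetric truncation keeps the window centred on the sample.
    for i in list(range(hw)) + list(range(n - hw, n)):
        r = min(i, hw, n - 1 - i)
        if r < 1:
            continue
        w = x[i - r : i + r + 1]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        if mad > 0 and abs(x[i] - med) > cfg.n_sigmas * MAD_SCALE * mad:
            out[i] = med
    return out


def hampel_filter_emg(
    rec: Recording, cfg: HampelConfig = HampelConfig()
) -> Recording:
    """Apply :func:`hampel_filter` to every EMG channel of a recording."""
    emg = np.column_stack(
        [hampel_filter(rec.emg[:, s], cfg) for s in range(rec.emg.shape[1])]
    )
    return replace_recording(rec, emg=emg)


def replace_recording(rec: Recording, **kwargs) -> Recording:
    fields = dict(
        emg=rec.emg,
        im=rec.im,
        labels=rec.labels,
        class_map=rec.class_map,
        layout=rec.layout,
        f_emg=rec.f_emg,
        f_im=rec.f_im,
        meta=rec.meta,
    )
    fields.update(kwargs)
    return Recording(**fields)


def synchronize(rec: Recording) -> AlignedRecording:
    """Linearly interpolate every IM channel onto the EMG sample grid.

    Outside the IM time span values are held at the nearest IM sample
    (constant extrapolation, never linear).
    """
    if rec.im.shape[0] < 2:
        raise ValidationError("synchronize needs at least 2 IM samples")
    t_emg = rec.emg_times()
    t_im = rec.im_times()
    im_sync = np.empty((t_emg.shape[0], rec.im.shape[1]))
    for j in range(rec.im.shape[1]):
        im_sync[:, j] = np.interp(t_emg, t_im, rec.im[:, j])
    return AlignedRecording(
        emg=rec.emg,
        im_on_emg_grid=im_sync,
        labels=rec.labels,
        class_map=rec.class_map,
        layout=rec.layout,
        f_emg=rec.f_emg,
        f_im=rec.f_im,
        meta=dict(rec.meta),
    )


def _segments(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous non-rest runs as (class, start, stop) sample triples."""
    out = []
    bounds = np.flatnonzero(np.diff(labels)) + 1
    edges = [0, *bounds.tolist(), labels.shape[0]]
    for a, b in zip(edges[:-1], edges[1:]):
        if labels[a] != 0:
            out.append((int(labels[a]), a, b))
    return out


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centred moving average with truncated edges (cumulative-sum based)."""
    width = max(1, width)
    half = width // 2
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = x.shape[0]
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def refine_labels(
    rec: Recording, search_ms: float = 500.0, smooth_ms: float = 50.0
) -> Recording:
    """Move each label boundary to the smoothed-power midpoint crossing.

    For every labelled segment, onset and offset are searched within
    ``±search_ms`` (clipped so adjacent segments are never crossed; a clipped
    window logs a warning) for the time where the multi-channel smoothed EMG
    power — the moving average of squared samples over ``smooth_ms``,
    averaged across channels — crosses the midpoint between the neighbouring
    rest level and the segment's active level. The class sequence and segment
    count are preserved; only boundary times move.
    """
    labels = rec.labels
    segs = _segments(labels)
    if not segs:
        raise ValidationError("refine_labels: recording contains no labelled segments")

    power = _moving_average(
        np.mean(rec.emg**2, axis=1), int(round(smooth_ms / 1000.0 * rec.f_emg))
    )
    n = labels.shape[0]
    search = int(round(search_ms / 1000.0 * rec.f_emg))

    new_labels = np.zeros_like(labels)
    prev_stop = 0  # labelled stop of the previous segment (pre-refinement)
    prev_new_stop = 0
    for k, (cls, start, stop) in enumerate(segs):
        next_start = segs[k + 1][1] if k + 1 < len(segs) else n
        active = float(np.median(power[start:stop]))
        rest_before = (
            float(np.median(power[prev_stop:start])) if start > prev_stop else 0.0
        )
        rest_after = (
            float(np.median(power[stop:next_start])) if next_start > stop else 0.0
        )

        # Search windows never cross the midpoint of an adjoining rest gap,
        # so refined segments cannot touch or swallow their neighbours.
        mid_before = (prev_stop + start) // 2
        mid_after = (stop + next_start) // 2
        lo = max(start - search, mid_before, prev_new_stop)
        hi = min(start + search, stop - 1)
        if lo > start - search or hi < start + search:
            log.warning("refine_labels: onset search window clipped at segment %d", k)
        thr = 0.5 * (rest_before + active)
        above = np.flatnonzero(power[lo : hi + 1] >= thr)
        new_start = lo + int(above[0]) if above.size else start

        lo2 = max(stop - search, new_start + 1)
        hi2 = min(stop + search, mid_after - 1)
        if lo2 > stop - search or hi2 < stop + search:
            log.warning("refine_labels: offset search window clipped at segment %d", k)
        thr2 = 0.5 * (rest_after + active)
        above2 = np.flatnonzero(power[lo2 : hi2 + 1] >= thr2)
        new_stop = lo2 + int(above2[-1]) + 1 if above2.size else stop

        new_labels[new_start:new_stop] = cls
        prev_stop = stop
        prev_new_stop = new_stop

    return replace_recording(rec, labels=new_labels)
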