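"""Class-structured synthetic sEMG + IM recordings with planted ground truth.

EMG is modelled as amplitude-modulated Gaussian noise: during a class-``c``
segment, sensor ``s`` carries zero-mean noise with standard deviation
``emg_gain[c, s] * noise_sd_emg`` (the standard surrogate for
interference-pattern EMG — downstream time-domain features depend only on
second-order statistics). IM class structure is carried by per-class channel
means (postural offsets), optionally with a linear coupling from the EMG
amplitude envelope into chosen IM channels, plus Gaussian noise.

The trial structure mirrors the offline protocol: an initial rest period,
then each class repeated ``n_repetitions`` times with a rest period after
every trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from emgimu.dataio import (
    N_IM_CHANNELS,
    Recording,
    SensorLayout,
)
from emgimu.errors import ValidationError

REALTIME_CLASS_NAMES = (
    "Rest",
    "Power",
    "Lateral",
    "Tripod",
    "Index pointer",
    "Open",
)


@dataclass
class SynthConfig:
    """Generator configuration.

    ``emg_gain`` rows index classes 0..n_classes (row 0 = rest baseline) and
    columns index sensors. ``im_offset`` rows likewise, columns index the
    ``9 * n_sensors`` IM channels. When either is ``None``, a seeded default
    is materialized in which only ``informative_sensors`` carry
    class-dependent structure.

    ``coupling`` is an optional length-9 vector applied identically to every
    sensor: IM channel ``j`` of sensor ``s`` receives
    ``coupling[j] * envelope_s(t)``, where ``envelope_s`` is the
    instantaneous EMG amplitude (sd) level of sensor ``s``.
    """

    n_classes: int = 40
    n_sensors: int = 12
    n_repetitions: int = 6
    trial_duration_s: float = 5.0
    rest_duration_s: float = 5.0
    f_emg: float = 2000.0
    f_im: float = 128.0
    emg_gain: Optional[np.ndarray] = None
    im_offset: Optional[np.ndarray] = None
    informative_sensors: Optional[Sequence[int]] = None  # 1-based
    noise_sd_emg: float = 0.1
    noise_sd_im: float = 0.05
    coupling: Optional[np.ndarray] = None
    powerline_amp: float = 0.0
    onset_jitter_ms: float = 0.0
    seed: int = 0
    class_names: Optional[Sequence[str]] = None  # names for 0..n_classes

    def validate(self) -> None:
        if self.n_classes < 1 or self.n_sensors < 1 or self.n_repetitions < 1:
            raise ValidationError("SynthConfig: counts must be >= 1")
        if self.trial_duration_s <= 0 or self.rest_duration_s <= 0:
            raise ValidationError("SynthConfig: durations must be positive")
        if not (self.f_emg > self.f_im > 0):
            raise ValidationError("SynthConfig: need f_emg > f_im > 0")
        if self.noise_sd_emg < 0 or self.noise_sd_im < 0:
            raise ValidationError("SynthConfig: noise sds must be >= 0")
        for name, mat, ncol in (
            ("emg_gain", self.emg_gain, self.n_sensors),
            ("im_offset", self.im_offset, N_IM_CHANNELS * self.n_sensors),
        ):
            if mat is not None:
                mat = np.asarray(mat, dtype=float)
                if mat.shape != (self.n_classes + 1, ncol):
                    raise ValidationError(
                        f"SynthConfig: {name} must have shape "
                        f"({self.n_classes + 1}, {ncol}), got {mat.shape}"
                    )
        if self.informative_sensors is not None:
            inf = set(self.informative_sensors)
            if not inf or not inf <= set(range(1, self.n_sensors + 1)):
                raise ValidationError(
                    "SynthConfig: informative_sensors must be a non-empty "
                    "subset of 1..n_sensors"
                )
        if self.coupling is not None:
            c = np.atleast_1d(np.asarray(self.coupling, dtype=float))
            if c.shape not in ((1,), (N_IM_CHANNELS,)):
                raise ValidationError(
                    "SynthConfig: coupling must be a scalar or length-9 vector"
                )
        if self.class_names is not None and len(self.class_names) != self.n_classes + 1:
            raise ValidationError(
                "SynthConfig: class_names must have n_classes + 1 entries"
            )


def default_configs(protocol: str) -> SynthConfig:
    """Named defaults for the two experimental protocols.

    ``"offline"``: 40 non-rest classes, 6 repetitions, 12 sensors, 5 s trials
    interleaved with 5 s rests. ``"realtime"``: 5 non-rest classes (power,
    lateral, tripod, index pointer, open) + rest, 5 repetitions, 12 sensors.
    """
    if protocol == "offline":
        return SynthConfig(n_classes=40, n_repetitions=6, n_sensors=12)
    if protocol == "realtime":
        return SynthConfig(
            n_classes=5,
            n_repetitions=5,
            n_sensors=12,
            class_names=REALTIME_CLASS_NAMES,
        )
    raise ValidationError(f"unknown protocol {protocol!r}; use 'offline' or 'realtime'")


def _materialize(cfg: SynthConfig, rng: np.random.Generator) -> SynthConfig:
    """Fill in seeded default gain/offset matrices (rest row = baseline)."""
    n_cls, n_sen = cfg.n_classes, cfg.n_sensors
    informative = (
        set(cfg.informative_sensors)
        if cfg.informative_sensors is not None
        else set(range(1, n_sen + 1))
    )

    if cfg.emg_gain is None:
        gain = np.ones((n_cls + 1, n_sen))
        gain[1:, :] = rng.uniform(2.0, 6.0, size=(n_cls, n_sen))
    else:
        gain = np.array(cfg.emg_gain, dtype=float)

    if cfg.im_offset is None:
        off = np.zeros((n_cls + 1, N_IM_CHANNELS * n_sen))
        off[1:, :] = rng.normal(0.0, 10.0 * cfg.noise_sd_im, size=(n_cls, off.shape[1]))
    else:
        off = np.array(cfg.im_offset, dtype=float)

    # Uninformative sensors repeat the rest row for every class so their
    # distributions carry no class information.
    for s in range(1, n_sen + 1):
        if s not in informative:
            gain[1:, s - 1] = gain[0, s - 1]
            cols = slice((s - 1) * N_IM_CHANNELS, s * N_IM_CHANNELS)
            off[1:, cols] = off[0, cols]

    return replace(cfg, emg_gain=gain, im_offset=off)


def _default_class_map(cfg: SynthConfig) -> dict[int, str]:
    if cfg.class_names is not None:
        return {i: str(name) for i, name in enumerate(cfg.class_names)}
    return {0: "Rest", **{c: f"Class {c:02d}" for c in range(1, cfg.n_classes + 1)}}


def _render(
    cfg: SynthConfig,
    labels_emg: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render EMG and IM arrays for a given per-EMG-sample label series."""
    n_emg = labels_emg.shape[0]
    n_im = int(round(n_emg * cfg.f_im / cfg.f_emg))
    n_sen = cfg.n_sensors

    gain = np.asarray(cfg.emg_gain, dtype=float)
    off = np.asarray(cfg.im_offset, dtype=float)

    sd_level = gain[labels_emg, :] * cfg.noise_sd_emg  # (n_emg, n_sensors)
    emg = rng.standard_normal((n_emg, n_sen)) * sd_level
    if cfg.powerline_amp:
        t = np.arange(n_emg) / cfg.f_emg
        emg += cfg.powerline_amp * np.sin(2 * np.pi * 50.0 * t)[:, None]

    # IM label series: nearest (left-aligned) EMG sample for each IM sample.
    idx = np.minimum((np.arange(n_im) * cfg.f_emg / cfg.f_im).astype(int), n_emg - 1)
    labels_im = labels_emg[idx]
    im = off[labels_im, :] + rng.normal(0.0, cfg.noise_sd_im, (n_im, N_IM_CHANNELS * n_sen))
    if cfg.coupling is not None:
        coup = np.broadcast_to(
            np.atleast_1d(np.asarray(cfg.coupling, dtype=float)), (N_IM_CHANNELS,)
        )
        env_im = gain[labels_im, :] * cfg.noise_sd_emg  # (n_im, n_sensors)
        # channel j of sensor s += coupling[j] * envelope_s
        im += np.repeat(env_im, N_IM_CHANNELS, axis=1) * np.tile(coup, n_sen)
    return emg, im


def generate_recording(cfg: SynthConfig) -> Recording:
    """Generate a full offline-protocol recording.

    Segment layout: rest, then for each class ``c = 1..n_classes`` a block of
    ``n_repetitions`` trials each followed by rest, for a total duration of
    ``n_classes * n_repetitions * (trial + rest) + rest`` seconds. The true
    (un-jittered) segment boundaries are recorded in
    ``meta["true_segments"]`` as ``[class, onset_s, offset_s]`` triples;
    ``onset_jitter_ms`` perturbs only the label series, exercising
    label-onset refinement downstream.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cfg = _materialize(cfg, rng)

    n_trial = int(round(cfg.trial_duration_s * cfg.f_emg))
    n_rest = int(round(cfg.rest_duration_s * cfg.f_emg))
    n_emg = cfg.n_classes * cfg.n_repetitions * (n_trial + n_rest) + n_rest

    labels = np.zeros(n_emg, dtype=int)
    true_segments: list[list[float]] = []
    pos = n_rest
    for c in range(1, cfg.n_classes + 1):
        for _ in range(cfg.n_repetitions):
            labels[pos : pos + n_trial] = c
            true_segments.append(
                [float(c), pos / cfg.f_emg, (pos + n_trial) / cfg.f_emg]
            )
            pos += n_trial + n_rest

    emg, im = _render(cfg, labels, rng)
    if cfg.onset_jitter_ms > 0:
        # Signals are rendered from the true boundaries; only the label
        # series is perturbed, mimicking stimulus-timing noise.
        labels = _jitter_labels(labels, cfg, rng)
    return Recording(
        emg=emg,
        im=im,
        labels=labels,
        class_map=_default_class_map(cfg),
        layout=SensorLayout.default(cfg.n_sensors),
        f_emg=cfg.f_emg,
        f_im=cfg.f_im,
        meta={
            "generator": "emgimu.synthetic_data",
            "seed": cfg.seed,
            "true_segments": true_segments,
            "onset_jitter_ms": cfg.onset_jitter_ms,
        },
    )


def _jitter_labels(
    labels: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Shift each segment boundary by U(-j, +j) while keeping order."""
    j = int(round(cfg.onset_jitter_ms / 1000.0 * cfg.f_emg))
    bounds = np.flatnonzero(np.diff(labels)) + 1  # indices where label changes
    edges = [0, *bounds.tolist(), labels.shape[0]]
    shifted = [0]
    for b in edges[1:-1]:
        nb = b + int(rng.integers(-j, j + 1))
        nb = max(nb, shifted[-1] + 1)
        nb = min(nb, labels.shape[0] - 1)
        shifted.append(nb)
    shifted.append(labels.shape[0])
    out = np.empty_like(labels)
    for k in range(len(shifted) - 1):
        out[shifted[k] : shifted[k + 1]] = labels[edges[k]]
    return out


@dataclass
class IntentTrace:
    """Ordered sequence of intended commands: (class, onset_s, offset_s)."""

    intents: list[tuple[int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for cls, on, off in self.intents:
            if off <= on:
                raise ValidationError(f"IntentTrace: interval ({on}, {off}) empty")
            if on < prev_end:
                raise ValidationError("IntentTrace: intervals overlap or not sorted")
            prev_end = off

    def __len__(self) -> int:
        return len(self.intents)

    def __iter__(self):
        return iter(self.intents)

    @property
    def classes(self) -> list[int]:
        return [c for c, _, _ in self.intents]

    def end_s(self) -> float:
        return self.intents[-1][2] if self.intents else 0.0


def generate_control_stream(
    cfg: SynthConfig,
    intents: IntentTrace,
    duration_s: Optional[float] = None,
) -> tuple[Recording, IntentTrace]:
    """Render a testing-phase stream realizing ``intents`` over rest.

    During each intent interval the signal statistics follow the intent's
    class; elsewhere they follow rest. The trace is returned unchanged for
    scoring. Default stream duration is the last intent offset plus one rest
    period.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cfg = _materialize(cfg, rng)

    if duration_s is None:
        duration_s = intents.end_s() + cfg.rest_duration_s
    for cls, on, off in intents:
        if on < 0 or off > duration_s:
            raise ValidationError(
                f"IntentTrace: interval ({on}, {off}) outside [0, {duration_s}]"
            )
        if not 0 <= cls <= cfg.n_classes:
            raise ValidationError(f"IntentTrace: unknown class {cls}")

    n_emg = int(round(duration_s * cfg.f_emg))
    labels = np.zeros(n_emg, dtype=int)
    for cls, on, off in intents:
        labels[int(round(on * cfg.f_emg)) : int(round(off * cfg.f_emg))] = cls

    emg, im = _render(cfg, labels, rng)
    rec = Recording(
        emg=emg,
        im=im,
        labels=labels,
        class_map=_default_class_map(cfg),
        layout=SensorLayout.default(cfg.n_sensors),
        f_emg=cfg.f_emg,
        f_im=cfg.f_im,
        meta={"generator": "emgimu.synthetic_data", "seed": cfg.seed, "stream": True},
    )
    return rec, intents
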