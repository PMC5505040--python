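"""Recording container and validated directory-of-CSV I/O.

A recording bundles one sEMG channel at ``f_emg`` (default 2 kHz) and nine
inertial-measurement (IM) channels at ``f_im`` (default 128 Hz) per sensor,
together with an integer label series on the EMG timeline (0 = rest).

On disk a recording is a directory containing ``meta.json``, ``emg.csv``,
``imu.csv`` and ``labels.csv``. CSV was chosen over a binary container so
fixtures stay human-inspectable; time columns are seconds from recording
start, samples left-aligned on their timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from emgimu.errors import ValidationError

#: Per-sensor IM channel order. The acquisition hardware does not impose one,
#: so this ordering is normative for the container.
IM_SUFFIXES = ("ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz")

#: Number of IM channels per sensor (tri-axial accelerometer, gyroscope,
#: magnetometer).
N_IM_CHANNELS = len(IM_SUFFIXES)

#: Default placement labels: ring of eight around the forearm, two extrinsic
#: hand-muscle sites, biceps and triceps.
DEFAULT_PLACEMENTS = tuple(
    [f"Forearm ring {i}" for i in range(1, 9)] + ["EDC", "FDS", "Biceps", "Triceps"]
)


@dataclass(frozen=True)
class SensorLayout:
    """Physical sensor arrangement.

    Parameters
    ----------
    n_sensors
        Number of combined EMG-IM sensor packages.
    placement_labels
        One human-readable location per sensor; must be unique.
    """

    n_sensors: int = 12
    placement_labels: tuple[str, ...] = DEFAULT_PLACEMENTS

    def __post_init__(self) -> None:
        if self.n_sensors < 1:
            raise ValidationError("SensorLayout: n_sensors must be >= 1")
        labels = tuple(self.placement_labels)
        object.__setattr__(self, "placement_labels", labels)
        if len(labels) != self.n_sensors:
            raise ValidationError(
                f"SensorLayout: {len(labels)} placement labels for "
                f"{self.n_sensors} sensors"
            )
        if len(set(labels)) != len(labels):
            raise ValidationError("SensorLayout: placement labels must be unique")

    @classmethod
    def default(cls, n_sensors: int = 12) -> "SensorLayout":
        """Layout with generic labels when the standard 12-sensor montage
        does not apply."""
        if n_sensors == 12:
            return cls()
        return cls(n_sensors, tuple(f"Sensor {i}" for i in range(1, n_sensors + 1)))


@dataclass
class Violation:
    """A single validation failure: which field, what was expected, what was
    observed."""

    field: str
    expectation: str
    observed: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: expected {self.expectation}, observed {self.observed}"


@dataclass
class Recording:
    """Multi-rate multi-channel recording with labels on the EMG timeline.

    ``emg`` has shape ``(n_emg_samples, n_sensors)``; ``im`` has shape
    ``(n_im_samples, 9 * n_sensors)`` with per-sensor channel blocks ordered
    as :data:`IM_SUFFIXES`, sensors in layout order. ``labels`` is an integer
    class series aligned with ``emg`` rows (0 = rest); every value must be a
    key of ``class_map``.
    """

    emg: np.ndarray
    im: np.ndarray
    labels: np.ndarray
    class_map: dict[int, str]
    layout: SensorLayout
    f_emg: float = 2000.0
    f_im: float = 128.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.im = np.asarray(self.im, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_sensors(self) -> int:
        return self.layout.n_sensors

    @property
    def duration_s(self) -> float:
        return self.emg.shape[0] / self.f_emg

    def emg_times(self) -> np.ndarray:
        return np.arange(self.emg.shape[0]) / self.f_emg

    def im_times(self) -> np.ndarray:
        return np.arange(self.im.shape[0]) / self.f_im

    def im_column_names(self) -> list[str]:
        return im_column_names(self.n_sensors)


def im_column_names(n_sensors: int) -> list[str]:
    """Canonical IM column names: ``s01_ax .. s01_mz, s02_ax, ...``."""
    return [
        f"s{s:02d}_{suf}" for s in range(1, n_sensors + 1) for suf in IM_SUFFIXES
    ]


def emg_column_names(n_sensors: int) -> list[str]:
    """Canonical EMG column names: ``s01 .. sNN``."""
    return [f"s{s:02d}" for s in range(1, n_sensors + 1)]


def validate_recording(rec: Recording) -> list[Violation]:
    """Check every Recording invariant; never raises.

    Returns
    -------
    list of :class:`Violation`
        Empty iff the recording is valid.
    """
    out: list[Violation] = []
    if not (rec.f_emg > rec.f_im > 0):
        out.append(
            Violation(
                "rates", "f_emg > f_im > 0", f"f_emg={rec.f_emg}, f_im={rec.f_im}"
            )
        )
    if rec.emg.ndim != 2 or rec.emg.shape[1] != rec.n_sensors:
        out.append(
            Violation(
                "emg",
                f"2-D array with {rec.n_sensors} columns",
                f"shape {rec.emg.shape}",
            )
        )
    n_im_cols = N_IM_CHANNELS * rec.n_sensors
    if rec.im.ndim != 2 or rec.im.shape[1] != n_im_cols:
        out.append(
            Violation(
                "im", f"2-D array with {n_im_cols} columns", f"shape {rec.im.shape}"
            )
        )
    if rec.labels.shape != (rec.emg.shape[0],):
        out.append(
            Violation(
                "labels",
                f"length {rec.emg.shape[0]} (= n_emg_samples)",
                f"shape {rec.labels.shape}",
            )
        )
    if rec.f_im > 0 and rec.f_emg > 0:
        dur_emg = rec.emg.shape[0] / rec.f_emg
        dur_im = rec.im.shape[0] / rec.f_im
        if abs(dur_emg - dur_im) > 1.0 / rec.f_im:
            out.append(
                Violation(
                    "durations",
                    "EMG and IM durations agree within one IM sample period",
                    f"{dur_emg:.6f} s (EMG) vs {dur_im:.6f} s (IM)",
                )
            )
    unknown = set(np.unique(rec.labels)) - set(rec.class_map)
    if unknown:
        out.append(
            Violation(
                "labels",
                "all label values present in class_map",
                f"unknown classes {sorted(unknown)}",
            )
        )
    return out


def _require_valid(rec: Recording) -> None:
    violations = validate_recording(rec)
    if violations:
        raise ValidationError(
            "invalid recording: " + "; ".join(str(v) for v in violations)
        )


_FLOAT_FMT = "%.10g"


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` to ``path`` as meta.json + emg.csv + imu.csv + labels.csv.

    The recording is validated first; a :class:`ValidationError` names the
    violated invariant. Values round-trip through :func:`read_recording` to
    the stored (10 significant digit) precision.
    """
    _require_valid(rec)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = {
        "f_emg": rec.f_emg,
        "f_im": rec.f_im,
        "n_sensors": rec.n_sensors,
        "placement_labels": list(rec.layout.placement_labels),
        "class_map": {str(k): v for k, v in rec.class_map.items()},
        "meta": rec.meta,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))

    emg_df = pd.DataFrame(rec.emg, columns=emg_column_names(rec.n_sensors))
    emg_df.insert(0, "time", rec.emg_times())
    emg_df.to_csv(path / "emg.csv", index=False, float_format=_FLOAT_FMT)

    im_df = pd.DataFrame(rec.im, columns=im_column_names(rec.n_sensors))
    im_df.insert(0, "time", rec.im_times())
    im_df.to_csv(path / "imu.csv", index=False, float_format=_FLOAT_FMT)

    lab_df = pd.DataFrame({"time": rec.emg_times(), "class": rec.labels})
    lab_df.to_csv(path / "labels.csv", index=False, float_format=_FLOAT_FMT)


def read_recording(path: str | Path) -> Recording:
    """Read a recording directory written by :func:`write_recording`.

    IM columns are normalized to the canonical per-sensor (ax..mz) order
    regardless of their order in the file. Missing files raise ``OSError``;
    malformed content raises :class:`ValidationError`.
    """
    path = Path(path)
    for fname in ("meta.json", "emg.csv", "imu.csv", "labels.csv"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"recording container missing {fname} in {path}")

    meta = json.loads((path / "meta.json").read_text())
    n_sensors = int(meta["n_sensors"])
    layout = SensorLayout(n_sensors, tuple(meta["placement_labels"]))
    class_map = {int(k): v for k, v in meta["class_map"].items()}

    emg_df = pd.read_csv(path / "emg.csv")
    want_emg = emg_column_names(n_sensors)
    missing = [c for c in want_emg if c not in emg_df.columns]
    if missing:
        raise ValidationError(f"emg.csv missing columns: {missing}")
    emg = emg_df[want_emg].to_numpy(dtype=float)

    im_df = pd.read_csv(path / "imu.csv")
    want_im = im_column_names(n_sensors)
    missing = [c for c in want_im if c not in im_df.columns]
    if missing:
        raise ValidationError(f"imu.csv missing columns: {missing}")
    im = im_df[want_im].to_numpy(dtype=float)

    lab_df = pd.read_csv(path / "labels.csv")
    if "class" not in lab_df.columns:
        raise ValidationError("labels.csv missing 'class' column")
    labels = lab_df["class"].to_numpy(dtype=int)

    rec = Recording(
        emg=emg,
        im=im,
        labels=labels,
        class_map=class_map,
        layout=layout,
        f_emg=float(meta["f_emg"]),
        f_im=float(meta["f_im"]),
        meta=dict(meta.get("meta", {})),
    )
    _require_valid(rec)
    return rec
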