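"""Finite-state controller and pick-and-place trial simulator.

The controller gates classifier posteriors: a command is emitted only when
the maximum posterior strictly exceeds the confidence threshold, the
previous movement has finished executing, and the predicted class differs
from the current hand pose. Movement execution is surrogated by a fixed
configurable duration (the physical hand's motor-current termination sensing
has no counterpart in simulation).

Trial scoring follows the user-correction convention: a wrong command
invalidates progress until an "open" command is issued, after which the
required sequence resumes where it left off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from emgimu.classification import LDAModel, predict_posterior
from emgimu.errors import ValidationError
from emgimu.evaluation import bootstrap_ci
from emgimu.features import (
    FeatureMatrix,
    Standardizer,
    WindowConfig,
    apply_standardizer,
    build_feature_matrix,
)
from emgimu.preprocessing import synchronize
from emgimu.dataio import Recording
from emgimu.synthetic_data import IntentTrace

REST_POSE = 0


@dataclass(frozen=True)
class ControllerConfig:
    theta: float = 0.995
    exec_duration_s: float = 1.0
    tick_s: float = 0.05  # the window increment

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.exec_duration_s <= 0 or self.tick_s <= 0:
            raise ValidationError("ControllerConfig: all parameters must be positive")


@dataclass(frozen=True)
class TrialConfig:
    """Task definition: ordered command sequence and time budget.

    The default sequence is the pick-and-place task: three grips each
    followed by an intermediate open, then the index-pointer key press —
    seven commands in total. ``open_class`` identifies the hand-open command
    used both in the required sequence and for error recovery.
    """

    time_limit_s: float = 60.0
    required_commands: tuple[int, ...] = (1, 5, 2, 5, 3, 5, 4)
    open_class: int = 5

    def __post_init__(self) -> None:
        if self.time_limit_s <= 0:
            raise ValidationError("TrialConfig: time_limit_s must be positive")
        if not self.required_commands:
            raise ValidationError("TrialConfig: required_commands must be non-empty")


@dataclass(frozen=True)
class FSMState:
    """Controller state: current hand pose and, while a movement executes,
    the time at which execution completes."""

    pose: int = REST_POSE
    executing_until: Optional[float] = None

    @property
    def executing(self) -> bool:
        return self.executing_until is not None


@dataclass
class TrialResult:
    success: bool
    completion_time_s: Optional[float]
    command_log: list[tuple[float, int]]
    rejection_fraction: float


def fsm_step(
    state: FSMState,
    posterior: np.ndarray,
    classes: np.ndarray,
    t: float,
    cfg: ControllerConfig = ControllerConfig(),
) -> tuple[FSMState, Optional[int]]:
    """Advance the controller by one decision tick.

    While executing, no command is emitted; the state returns to idle once
    ``t`` reaches the execution deadline (the new pose is retained). When
    idle, a command is emitted iff the maximum posterior strictly exceeds
    ``theta`` and the winning class is a movement (not rest) differing from
    the current hand pose; the controller then executes for
    ``exec_duration_s``. A confident rest prediction means "hold", never a
    command.
    """
    posterior = np.asarray(posterior, dtype=float)
    if abs(posterior.sum() - 1.0) > 1e-6:
        raise ValidationError("fsm_step: posterior does not sum to 1")
    if state.executing:
        if t >= state.executing_until:
            state = FSMState(pose=state.pose, executing_until=None)
        else:
            return state, None
    best = int(np.argmax(posterior))
    if posterior[best] > cfg.theta:
        cls = int(classes[best])
        if cls != REST_POSE and cls != state.pose:
            return FSMState(pose=cls, executing_until=t + cfg.exec_duration_s), cls
    return state, None


def score_command_log(
    command_log: Sequence[tuple[float, int]], tc: TrialConfig
) -> tuple[bool, Optional[float]]:
    """Check whether a command log realizes the required sequence.

    A command matching the next required one advances progress. Any other
    command puts the trial into an error state that only an ``open`` command
    clears (the correction open does not count toward a required open).
    Returns (success, completion time = time of the final required command).
    """
    ptr = 0
    error = False
    for t, cmd in command_log:
        if t > tc.time_limit_s:
            break
        if error:
            if cmd == tc.open_class:
                error = False
            continue
        if cmd == tc.required_commands[ptr]:
            ptr += 1
            if ptr == len(tc.required_commands):
                return True, float(t)
        else:
            error = True
    return False, None


def run_controller(
    posteriors: np.ndarray,
    times: np.ndarray,
    classes: np.ndarray,
    cc: ControllerConfig = ControllerConfig(),
) -> tuple[list[tuple[float, int]], float]:
    """Run the FSM over a posterior stream; returns (command log,
    rejection fraction — the share of ticks whose maximum posterior did not
    clear the threshold)."""
    state = FSMState()
    log: list[tuple[float, int]] = []
    rejected = 0
    for p, t in zip(posteriors, times):
        if p.max() <= cc.theta:
            rejected += 1
        state, cmd = fsm_step(state, p, classes, float(t), cc)
        if cmd is not None:
            log.append((float(t), cmd))
    frac = rejected / len(times) if len(times) else 0.0
    return log, frac


def simulate_trial(
    model: LDAModel,
    stream: tuple[Recording, IntentTrace],
    cc: ControllerConfig = ControllerConfig(),
    tc: TrialConfig = TrialConfig(),
    *,
    standardizer: Standardizer,
    window: WindowConfig = WindowConfig(),
    modality: str = "both",
    sensors: Optional[Sequence[int]] = None,
) -> TrialResult:
    """Run the full decoding pipeline over a signal stream, tick by tick.

    The stream is synchronized, windowed and featurized exactly as during
    training, standardized with the *training* statistics, classified, and
    fed through the finite-state controller. Success requires the command
    log to realize ``tc.required_commands`` in order within the time limit
    under the correction rule of :func:`score_command_log`. Deterministic
    given the stream and model.
    """
    rec, _intents = stream
    ar = synchronize(rec)
    F = build_feature_matrix(ar, window, modality=modality, sensors=sensors)
    Fz = apply_standardizer(standardizer, F)
    if Fz.d != model.d:
        raise ValidationError(
            f"simulate_trial: model expects {model.d} features, stream yields {Fz.d}"
        )
    posteriors = predict_posterior(model, Fz.X)
    log, rej = run_controller(posteriors, Fz.t, model.classes, cc)
    success, ct = score_command_log(log, tc)
    return TrialResult(
        success=success,
        completion_time_s=ct,
        command_log=log,
        rejection_fraction=rej,
    )


@dataclass
class CompletionMetrics:
    cr: float  # completion rate, percent
    ct_mean: Optional[float]  # mean completion time over successes (s)
    ct_ci: Optional[tuple[float, float]]  # bootstrap CI; None if < 2 successes


def completion_metrics(
    results: Sequence[TrialResult],
    n_boot: int = 100,
    seed: Optional[int] = None,
) -> CompletionMetrics:
    """Completion rate and completion-time statistics over a trial set.

    CT statistics are computed over successful trials only; with a single
    success the mean is reported without a confidence interval, and with no
    successes CT is undefined (``None``).
    """
    if not results:
        raise ValidationError("completion_metrics: empty result collection")
    n = len(results)
    cts = [r.completion_time_s for r in results if r.success]
    cr = 100.0 * len(cts) / n
    if not cts:
        return CompletionMetrics(cr=cr, ct_mean=None, ct_ci=None)
    ct_mean = float(np.mean(cts))
    ci = bootstrap_ci(np.asarray(cts), n_boot=n_boot, seed=seed) if len(cts) >= 2 else None
    return CompletionMetrics(cr=cr, ct_mean=ct_mean, ct_ci=ci)
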