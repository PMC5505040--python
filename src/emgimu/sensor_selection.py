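"""Grouped sequential forward sensor selection with fold-majority voting.

Sensors are added greedily, whole feature blocks at a time (16 columns per
sensor when both modalities are present, 7 or 9 for a single modality). At
every step each cross-validation fold votes for the candidate sensor that
maximizes that fold's accuracy; the sensor with most votes joins the pool.
The procedure runs until all sensors are ranked; a separate marginal-gain
rule then picks the working subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from emgimu.classification import fit_lda, predict
from emgimu.errors import ValidationError
from emgimu.evaluation import CVConfig, balance_rest, classification_accuracy, repetition_folds
from emgimu.features import FeatureMatrix, apply_standardizer, fit_standardizer


@dataclass(frozen=True)
class SelectionConfig:
    """Forward-selection parameters.

    ``gain_threshold`` is in accuracy percentage points: the subset rule
    stops at the first sensor whose addition improves mean CA by no more
    than this amount. ``cv.k`` defaults to 3 — selection typically runs on
    training data with few repetitions.
    """

    gain_threshold: float = 1.0
    cv: CVConfig = field(default_factory=lambda: CVConfig(k=3))
    shrinkage: float = 1e-3
    balance: bool = False
    mode: str = "prefix"  # "prefix" | "any" subset rule

    def __post_init__(self) -> None:
        if self.gain_threshold < 0:
            raise ValidationError("SelectionConfig: gain_threshold must be >= 0")
        if self.mode not in ("prefix", "any"):
            raise ValidationError("SelectionConfig: mode must be 'prefix' or 'any'")


@dataclass
class SelectionResult:
    ranking: list[int]  # sensors in order of addition (all sensors)
    ca_curve: np.ndarray  # mean cross-validated CA after each addition
    per_step_votes: list[dict[int, int]]  # candidate -> fold votes, per step
    subset: list[int]  # selected prefix (or gain-filtered set)


def _fold_cas(
    F: FeatureMatrix,
    cols: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    cfg: SelectionConfig,
) -> np.ndarray:
    """Per-fold CA for a fixed column subset (standardizer and classifier
    refitted per fold)."""
    cas = np.empty(len(folds))
    for i, (train, test) in enumerate(folds):
        Fc = F.restrict(cols=cols)
        S = fit_standardizer(Fc, train)
        Fz = apply_standardizer(S, Fc)
        model = fit_lda(Fz.X[train], Fz.y[train], shrinkage=cfg.shrinkage)
        rows = balance_rest(F, test) if cfg.balance else test
        pred = predict(model, Fz.X[rows])
        cas[i] = classification_accuracy(np.atleast_1d(pred), Fz.y[rows])
    return cas


def sfss_rank(F: FeatureMatrix, cfg: SelectionConfig = SelectionConfig()) -> SelectionResult:
    """Rank all sensors by greedy forward selection with fold voting.

    Starting from the empty pool, every remaining sensor is evaluated by
    adding its full feature block; each fold votes for its best candidate
    (within-fold CA ties go to the lower sensor index). The candidate with
    most votes is added — vote ties broken by higher mean CA across folds,
    then lower sensor index. ``ca_curve[i]`` is the mean CA after the
    ``i+1``-th addition. Deterministic given ``F`` and ``cfg``.
    """
    sensors = F.sensors()
    if len(sensors) < 2:
        raise ValidationError("sfss_rank: need at least 2 sensors")
    folds = repetition_folds(F, cfg.cv)

    selected: list[int] = []
    selected_cols: list[int] = []
    curve: list[float] = []
    votes_log: list[dict[int, int]] = []

    remaining = list(sensors)
    while remaining:
        cand_cas: dict[int, np.ndarray] = {}
        for s in remaining:
            cols = np.concatenate([selected_cols, F.sensor_block(s)]).astype(int)
            cand_cas[s] = _fold_cas(F, cols, folds, cfg)

        n_folds = len(folds)
        votes = {s: 0 for s in remaining}
        for f in range(n_folds):
            best_ca = max(cand_cas[s][f] for s in remaining)
            # within-fold tie -> lower sensor index
            winner = min(s for s in remaining if cand_cas[s][f] == best_ca)
            votes[winner] += 1
        votes_log.append(dict(votes))

        max_votes = max(votes.values())
        tied = [s for s in remaining if votes[s] == max_votes]
        if len(tied) > 1:
            best_mean = max(float(np.mean(cand_cas[s])) for s in tied)
            tied = [s for s in tied if float(np.mean(cand_cas[s])) == best_mean]
        winner = min(tied)

        selected.append(winner)
        selected_cols = np.concatenate([selected_cols, F.sensor_block(winner)]).astype(int).tolist()
        curve.append(float(np.mean(cand_cas[winner])))
        remaining.remove(winner)

    result = SelectionResult(
        ranking=selected,
        ca_curve=np.asarray(curve),
        per_step_votes=votes_log,
        subset=[],
    )
    result.subset = select_subset(result, cfg)
    return result


def select_subset(r: SelectionResult, cfg: SelectionConfig = SelectionConfig()) -> list[int]:
    """Apply the marginal-gain stopping rule to a completed ranking.

    ``prefix`` mode (default) returns the ranking prefix ending just before
    the first addition whose CA gain is <= ``gain_threshold``; the first
    sensor is always included. ``any`` mode keeps the first sensor plus every
    later sensor whose individual gain exceeds the threshold (possibly
    non-contiguous).
    """
    gains = np.diff(r.ca_curve)
    if cfg.mode == "prefix":
        size = 1
        for g in gains:
            if g > cfg.gain_threshold:
                size += 1
            else:
                break
        return r.ranking[:size]
    keep = [r.ranking[0]]
    keep += [r.ranking[i + 1] for i, g in enumerate(gains) if g > cfg.gain_threshold]
    return keep
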