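"""Calibration of stage-specific symptom probabilities.

In an unscreened population incident cancers surface only on symptomatic
presentation, so the stage distribution of presenting cases is determined
jointly by the stage-progression rates and the per-stage symptom
probabilities.  Given a target stage distribution (e.g. the registry
distribution of newly reported cases), the calibration adjusts the four
symptom probabilities until the model's presentation distribution matches.

The search is a derivative-free Nelder-Mead simplex on logit-transformed
probabilities minimising the L2 distance between distributions, started
from the supplied (default: currently configured) symptom probabilities
with scipy's deterministic initial simplex.  Note the map from four
symptom probabilities to a three-degree-of-freedom distribution is not
injective, so the recovered vector is the solution nearest the starting
point along the feasible set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .cohort import run_cohort
from .errors import (ConvergenceError, DegenerateDistributionError,
                     ValidationError)
from .parameters import STAGES, LifeTable, ModelParameters, no_screening


@dataclass(frozen=True)
class StageDistribution:
    """Proportions of symptomatic presentations occurring at stages I-IV."""

    proportions: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.proportions, dtype=float)
        if arr.shape != (4,):
            raise ValidationError("a stage distribution has four proportions")
        if np.any(arr < 0):
            raise ValidationError("stage proportions must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"stage proportions must sum to 1, got {arr.sum():.12f}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.proportions, dtype=float)


def _with_symptom_probs(params: ModelParameters, probs: np.ndarray
                        ) -> ModelParameters:
    d = params.to_dict()
    d["symptom_prob"] = {s: float(p) for s, p in zip(STAGES, probs)}
    return ModelParameters.from_dict(d)


def presentation_distribution(symptom_prob, params: ModelParameters,
                              life_table: LifeTable) -> StageDistribution:
    """Stage distribution of first symptomatic presentations, no screening."""
    probs = np.asarray(symptom_prob, dtype=float)
    if probs.shape != (4,):
        raise ValidationError("symptom_prob must have four entries")
    result = run_cohort(no_screening(), _with_symptom_probs(params, probs),
                        life_table)
    tallies = result.symptom_presentations_by_stage
    total = tallies.sum()
    if total <= 0:
        raise DegenerateDistributionError(
            "no symptomatic presentations occur; cannot form a stage "
            "distribution (are all symptom probabilities zero?)")
    return StageDistribution(tuple(tallies / total))


def calibrate_symptom_probs(target: StageDistribution,
                            params: ModelParameters,
                            life_table: LifeTable,
                            init=None,
                            tol: float = 1e-4,
                            max_iter: int = 600) -> np.ndarray:
    """Recover symptom probabilities reproducing ``target``.

    Deterministic given its inputs.  Raises :class:`ConvergenceError`
    carrying the best residual if the L2 distance cannot be brought under
    ``tol`` within ``max_iter`` objective evaluations.
    """
    if tol <= 0:
        raise ValidationError("tol must be positive")
    target_arr = target.as_array()
    if init is None:
        init = params.symptom_array()
    x0 = logit(np.clip(np.asarray(init, dtype=float), 1e-6, 1.0 - 1e-6))

    def objective(x: np.ndarray) -> float:
        dist = presentation_distribution(expit(x), params, life_table)
        return float(np.linalg.norm(dist.as_array() - target_arr))

    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxfev": max_iter, "xatol": 1e-6,
                            "fatol": tol / 10.0})
    best = expit(res.x)
    residual = objective(res.x)
    if residual > tol:
        raise ConvergenceError(
            f"calibration did not reach tol={tol}: best residual {residual:.3e}",
            best_residual=residual, best_probs=best)
    return best
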