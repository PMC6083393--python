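"""A screening round applied to the cohort occupancy vector.

Every living, not-yet-diagnosed woman attends (questionnaire + screening
cost).  Preclinical disease (DCIS or invasive) is detected with the
modality combination's sensitivity and confirmed by biopsy, which is
assumed perfectly accurate; healthy women screen falsely positive with
probability 1 - specificity, undergo biopsy and suffer a one-cycle
multiplicative utility decrement.  Detected invasive cases move to the
treated state (one-time stage treatment cost) with probability
``treatment_uptake``, otherwise to the diagnosed-untreated state; detected
DCIS is treated with the same uptake and otherwise remains in situ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError
from .parameters import ModelParameters, Strategy
from .states import (DIAG_BY_STAGE, N_STATES, PRECLINICAL_INVASIVE,
                     TREATED_BY_STAGE, UNDIAGNOSED_STATES, HealthState as S)


def test_characteristics(age: int, strategy: Strategy,
                         params: ModelParameters
                         ) -> tuple[float, float] | None:
    """(sensitivity, specificity) for the woman's age band; None outside
    the eligible range (a not-screened signal, not an error)."""
    combo = strategy.modality_for_age(age)
    if combo is None:
        return None
    perf = params.test_perf[combo]
    return perf["sensitivity"].baseline, perf["specificity"].baseline


@dataclass
class ScreeningRound:
    """Result of one screening round on an occupancy vector.

    Costs and the false-positive disutility are undiscounted per-cycle
    expectations per woman in the entering cohort; the cohort engine
    applies the discount factor of the cycle.
    """

    occupancy: np.ndarray
    cost: float = 0.0
    disutility: float = 0.0
    screen_detected: float = 0.0          # invasive diagnoses + treated DCIS
    detected_by_stage: np.ndarray = field(
        default_factory=lambda: np.zeros(4))
    dcis_detected: float = 0.0
    false_positives: float = 0.0
    attended: float = 0.0


def apply_screening_round(occupancy: np.ndarray, age: int,
                          strategy: Strategy, params: ModelParameters
                          ) -> ScreeningRound:
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.shape != (N_STATES,):
        raise ConsistencyError(
            f"occupancy vector must have length {N_STATES}")
    if np.any(occupancy < -1e-12) or occupancy.sum() > 1.0 + 1e-9:
        raise ConsistencyError(
            "occupancy vector is negative or exceeds total cohort mass")

    perf = test_characteristics(age, strategy, params)
    if perf is None:
        return ScreeningRound(occupancy=occupancy.copy())
    sens, spec = perf
    uptake = strategy.treatment_uptake

    c_quest = params.costs["questionnaire"].baseline
    c_screen = params.costs["screening"].baseline
    c_biopsy = params.costs["biopsy"].baseline
    c_treat = params.treatment_cost_array()   # dcis, I-IV

    occ = occupancy.copy()
    out = ScreeningRound(occupancy=occ)
    out.attended = float(sum(occupancy[s] for s in UNDIAGNOSED_STATES))
    out.cost = out.attended * (c_quest + c_screen)

    # false positives among healthy attendees: biopsy + one-cycle disutility
    fp = occupancy[S.HEALTHY] * (1.0 - spec)
    out.false_positives = float(fp)
    out.cost += fp * c_biopsy
    out.disutility = float(fp * params.disutility_fp.baseline
                           * params.fp_disutility_duration_years)

    # detected DCIS: biopsy for all detections; treated fraction pays the
    # DCIS treatment cost, the rest stays in situ undiagnosed
    det_dcis = occupancy[S.DCIS] * sens
    out.cost += det_dcis * c_biopsy
    treated_dcis = det_dcis * uptake
    occ[S.DCIS] -= treated_dcis
    occ[S.TREATED_DCIS] += treated_dcis
    out.cost += treated_dcis * c_treat[0]
    out.dcis_detected = float(treated_dcis)

    # detected invasive disease: biopsy, then treated / diagnosed-untreated
    for stage, state in enumerate(PRECLINICAL_INVASIVE):
        det = occupancy[state] * sens
        out.cost += det * c_biopsy
        occ[state] -= det
        occ[TREATED_BY_STAGE[stage]] += det * uptake
        occ[DIAG_BY_STAGE[stage]] += det * (1.0 - uptake)
        out.cost += det * uptake * c_treat[1 + stage]
        out.detected_by_stage[stage] = det

    out.screen_detected = float(out.detected_by_stage.sum() + treated_dcis)
    if abs(occ.sum() - occupancy.sum()) > 1e-9:
        raise ConsistencyError("screening round did not conserve cohort mass")
    return out
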