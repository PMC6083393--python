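"""Lifetime annual-cycle Markov cohort engine.

A cohort of women enters healthy at age 40 and is followed to age 100
(absorbing horizon).  Each annual cycle accrues utility to the states
occupied at the start of the cycle, then applies in order: other-cause
death, breast-cancer death, a screening round when the strategy schedules
one at this age, symptomatic presentation, and onset/progression.  Costs
(screening round, biopsy, one-time treatment at diagnosis) are charged in
the cycle they occur; costs and QALYs are discounted at the configured
annual rate with cycle 0 at age 40 undiscounted.

Utility convention: healthy women, in-situ (DCIS) carriers and treated
DCIS carry utility 1.0; invasive disease carries the stage utility from
onset (preclinical, treated and diagnosed-untreated alike), so the score
reflects the disease state rather than awareness of it.  Setting
``preclinical_stage_utility: false`` in the configuration restores
utility 1.0 for undiagnosed invasive stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .natural_history import (bc_death_matrix, other_cause_matrix,
                              progression_matrix, symptom_matrix)
from .parameters import (AGE_MAX, AGE_MIN, LifeTable, ModelParameters,
                         Strategy, onset_probability)
from .screening import apply_screening_round
from .states import (DIAG_BY_STAGE, N_STATES, PRECLINICAL_INVASIVE,
                     TREATED_BY_STAGE, HealthState as S)


def discount_factor(years_since_entry: int, rate: float) -> float:
    """Present-value factor 1/(1+rate)^t with t in whole years from age 40."""
    if years_since_entry < 0:
        raise DomainError("discounting is defined for t >= 0 only")
    return 1.0 / (1.0 + rate) ** years_since_entry


def utility_vector(params: ModelParameters) -> np.ndarray:
    u = np.zeros(N_STATES)
    u[S.HEALTHY] = 1.0
    u[S.DCIS] = 1.0
    u[S.TREATED_DCIS] = 1.0
    stage_u = params.utility_array()
    for stage in range(4):
        u[TREATED_BY_STAGE[stage]] = stage_u[stage]
        u[DIAG_BY_STAGE[stage]] = stage_u[stage]
        u[PRECLINICAL_INVASIVE[stage]] = (
            stage_u[stage] if params.preclinical_stage_utility else 1.0)
    return u


@dataclass
class CohortResult:
    """Lifetime outcomes per woman entering the cohort at age 40."""

    strategy: str
    discounted_cost: float
    discounted_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    counts_per_1000: dict[str, float]
    trace: pd.DataFrame
    symptom_presentations_by_stage: np.ndarray
    screen_detections_by_stage: np.ndarray

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {
            "strategy": self.strategy,
            "discounted_cost": self.discounted_cost,
            "discounted_qaly": self.discounted_qaly,
            "undiscounted_cost": self.undiscounted_cost,
            "undiscounted_qaly": self.undiscounted_qaly,
        }
        row.update(self.counts_per_1000)
        return row


def run_cohort(strategy: Strategy, params: ModelParameters,
               life_table: LifeTable) -> CohortResult:
    """Deterministic state-occupancy recursion over the lifetime horizon."""
    if not life_table.covers(AGE_MIN, AGE_MAX):
        raise DomainError(
            f"life table must cover ages {AGE_MIN}-{AGE_MAX}, got "
            f"{life_table.start_age}-{life_table.max_age}")

    rr_override = None
    if not strategy.is_screening and not params.rr_comparator_applies:
        rr_override = 1.0

    uptake = strategy.treatment_uptake
    v = 1.0 / (1.0 + params.discount_rate)
    util = utility_vector(params)
    sym = params.symptom_array()
    c_treat = params.treatment_cost_array()

    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    n_cycles = len(ages)
    m_bc = bc_death_matrix(params)
    m_sym = symptom_matrix(params, uptake)

    occ = np.zeros(N_STATES)
    occ[S.HEALTHY] = 1.0
    trace = np.zeros((n_cycles, N_STATES))
    cycle_utility = np.zeros(n_cycles)

    cost_d = cost_u = 0.0
    qaly_event_d = qaly_event_u = 0.0   # false-positive decrements
    sym_by_stage = np.zeros(4)
    scr_by_stage = np.zeros(4)
    onsets = dcis_detected = bc_deaths_prev = 0.0
    screen_detected = 0.0

    for t, age in enumerate(ages):
        trace[t] = occ
        cycle_utility[t] = float(occ @ util)

        # 1-2: deaths
        occ = occ @ other_cause_matrix(int(age), life_table) @ m_bc

        # 3: screening round
        if strategy.schedules(int(age)):
            rnd = apply_screening_round(occ, int(age), strategy, params)
            occ = rnd.occupancy
            dt = v ** t
            cost_d += dt * rnd.cost
            cost_u += rnd.cost
            qaly_event_d -= dt * rnd.disutility
            qaly_event_u -= rnd.disutility
            scr_by_stage += rnd.detected_by_stage
            dcis_detected += rnd.dcis_detected
            screen_detected += rnd.screen_detected

        # 4: symptomatic presentation (treatment cost charged at diagnosis)
        flows = np.array([occ[s] for s in PRECLINICAL_INVASIVE]) * sym
        sym_by_stage += flows
        treat_cost = float(flows @ c_treat[1:]) * uptake
        cost_d += v ** t * treat_cost
        cost_u += treat_cost
        occ = occ @ m_sym

        # 5: onset and progression
        p_inv = onset_probability(int(age), params, "invasive", rr_override)
        onsets += occ[S.HEALTHY] * p_inv \
            + occ[S.DCIS] * min(params.rr_dcis_to_invasive * p_inv, 1.0)
        occ = occ @ progression_matrix(int(age), params, rr_override)

    disc = v ** np.arange(n_cycles)
    if params.half_cycle_correction:
        # trapezoidal state-utility stream; event decrements unchanged
        padded = np.append(cycle_utility, 0.0)
        stream = 0.5 * (padded[:-1] + padded[1:])
    else:
        stream = cycle_utility
    qaly_d = float(stream @ disc) + qaly_event_d
    qaly_u = float(stream.sum()) + qaly_event_u

    symptom_detected = float(sym_by_stage.sum())
    counts = {
        "incident_cases": 1000.0 * (screen_detected + symptom_detected),
        "screen_detected": 1000.0 * screen_detected,
        "symptom_detected": 1000.0 * symptom_detected,
        "invasive_onsets": 1000.0 * onsets,
        "dcis_detected": 1000.0 * dcis_detected,
        "bc_deaths": 1000.0 * float(occ[S.BC_DEATH]),
    }
    trace_df = pd.DataFrame(trace, columns=[s.name for s in S])
    trace_df.insert(0, "age", ages)
    return CohortResult(
        strategy=strategy.name,
        discounted_cost=cost_d,
        discounted_qaly=qaly_d,
        undiscounted_cost=cost_u,
        undiscounted_qaly=qaly_u,
        counts_per_1000=counts,
        trace=trace_df,
        symptom_presentations_by_stage=sym_by_stage,
        screen_detections_by_stage=scr_by_stage,
    )
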