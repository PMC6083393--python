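"""Annual transition structure of the breast-cancer natural-history model.

Healthy women may develop ductal carcinoma in situ (DCIS) or stage I
invasive cancer; DCIS elevates the invasive onset risk (relative risk
2.02); invasive disease progresses strictly through stages I-IV; only
stage IV kills via breast cancer in the untreated pathway, while treated
women face a stage-specific post-treatment fatality.  Everyone alive is
exposed to other-cause mortality from the life table.

Competing events within a one-year cycle are applied sequentially, each
conditioned on the earlier ones not firing, in the fixed order:

1. other-cause death, 2. breast-cancer death, 3. scheduled screening
(handled by the cohort engine, not by these matrices), 4. symptomatic
presentation, 5. onset and stage progression.

This sequential-conditional convention keeps every annual matrix exactly
row-stochastic without renormalisation, and both the cohort recursion and
the individual-level simulation implement it identically.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError
from .parameters import LifeTable, ModelParameters, Strategy, onset_probability
from .states import (DIAG_BY_STAGE, N_STATES, PRECLINICAL_INVASIVE,
                     TREATED_BY_STAGE, HealthState as S)


def other_cause_matrix(age: int, life_table: LifeTable) -> np.ndarray:
    """Step 1: every living state loses the life-table mass to OtherDeath."""
    if not (life_table.start_age <= age <= life_table.max_age):
        raise DomainError(
            f"life table does not cover age {age} "
            f"(covers {life_table.start_age}-{life_table.max_age})")
    q = life_table.q_at(age)
    m = np.eye(N_STATES)
    for s in S:
        if s in (S.BC_DEATH, S.OTHER_DEATH):
            continue
        m[s, s] = 1.0 - q
        m[s, S.OTHER_DEATH] = q
    return m


def bc_death_matrix(params: ModelParameters) -> np.ndarray:
    """Step 2: breast-cancer death.

    Untreated (preclinical or diagnosed-untreated) stage IV dies at the
    untreated stage IV fatality; treated stages die at their post-treatment
    fatality rates.  Earlier untreated stages cannot die of breast cancer.
    """
    m = np.eye(N_STATES)
    f_iv = params.stage_iv_fatality_untreated
    for state in (S.PRE_IV, S.DIAG_IV):
        m[state, state] = 1.0 - f_iv
        m[state, S.BC_DEATH] = f_iv
    fatal = params.fatality_array()
    for stage, state in enumerate(TREATED_BY_STAGE):
        m[state, state] = 1.0 - fatal[stage]
        m[state, S.BC_DEATH] = fatal[stage]
    return m


def symptom_matrix(params: ModelParameters, treatment_uptake: float = 1.0
                   ) -> np.ndarray:
    """Step 4: symptomatic presentation of preclinical invasive disease.

    A presenting woman is diagnosed; she moves to the treated state with
    probability ``treatment_uptake`` and otherwise to the corresponding
    diagnosed-untreated state.  DCIS is asymptomatic and only detectable
    by screening.
    """
    m = np.eye(N_STATES)
    sym = params.symptom_array()
    for stage, state in enumerate(PRECLINICAL_INVASIVE):
        p = sym[stage]
        m[state, state] = 1.0 - p
        m[state, TREATED_BY_STAGE[stage]] = p * treatment_uptake
        m[state, DIAG_BY_STAGE[stage]] = p * (1.0 - treatment_uptake)
    return m


def progression_matrix(age: int, params: ModelParameters,
                       rr_override: float | None = None) -> np.ndarray:
    """Step 5: onset and stage progression.

    Healthy -> preclinical stage I at the invasive onset probability, else
    Healthy -> DCIS at the DCIS onset probability; DCIS -> preclinical
    stage I at RR_dcis x the invasive onset probability.  Undiagnosed and
    diagnosed-untreated invasive disease advances one stage per year at the
    stage progression rates; treated disease does not progress.
    """
    p_inv = onset_probability(age, params, "invasive", rr_override)
    p_dcis = onset_probability(age, params, "dcis", rr_override)
    prog = params.progression_array()
    m = np.eye(N_STATES)

    m[S.HEALTHY, S.PRE_I] = p_inv
    m[S.HEALTHY, S.DCIS] = (1.0 - p_inv) * p_dcis
    m[S.HEALTHY, S.HEALTHY] = 1.0 - p_inv - (1.0 - p_inv) * p_dcis

    p_dcis_inv = min(params.rr_dcis_to_invasive * p_inv, 1.0)
    m[S.DCIS, S.PRE_I] = p_dcis_inv
    m[S.DCIS, S.DCIS] = 1.0 - p_dcis_inv

    for chain in (PRECLINICAL_INVASIVE, DIAG_BY_STAGE):
        for stage in range(3):
            state, nxt = chain[stage], chain[stage + 1]
            m[state, state] = 1.0 - prog[stage]
            m[state, nxt] = prog[stage]
    return m


def build_transition_matrix(age: int, params: ModelParameters,
                            life_table: LifeTable,
                            strategy: Strategy | None = None,
                            rr_override: float | None = None) -> np.ndarray:
    """Composed annual transition matrix for a non-screening cycle.

    The product of the sequential-conditional steps (other-cause death,
    breast-cancer death, symptomatic presentation, onset/progression) in
    row-vector convention: ``occupancy_next = occupancy @ M``.  Screening
    rounds are applied separately by the cohort engine between the death
    and symptom steps.
    """
    uptake = strategy.treatment_uptake if strategy is not None else 1.0
    return (other_cause_matrix(age, life_table)
            @ bc_death_matrix(params)
            @ symptom_matrix(params, uptake)
            @ progression_matrix(age, params, rr_override))
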