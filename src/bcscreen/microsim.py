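"""Individual-level Monte-Carlo oracle and synthetic input generators.

The microsimulation re-implements the same natural-history, screening and
accrual conventions as the cohort engine by sampling one woman at a time
(vectorised across women), without sharing any of the transition-matrix
code.  Its sample means converge to the cohort engine's expectations, so
agreement between the two is independent evidence that both are right.

Also here: a Gompertz synthetic life-table generator standing in for a
national female life table, and a seeded random-parameter-set generator
used by the property-test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (AGE_MAX, AGE_MIN, LifeTable, ModelParameters,
                         Strategy, default_parameters, onset_probability)
from .cohort import utility_vector
from .errors import ValidationError
from .screening import test_characteristics
from .states import (DIAG_BY_STAGE, PRECLINICAL_INVASIVE, TREATED_BY_STAGE,
                     HealthState as S)


@dataclass
class MicrosimResult:
    """Sample means with standard errors from an individual-level run."""

    n_women: int
    seed: int
    strategy: str
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    counts_per_1000: dict[str, float]


def simulate_cohort(n_women: int, seed: int, strategy: Strategy,
                    params: ModelParameters, life_table: LifeTable
                    ) -> MicrosimResult:
    """Simulate ``n_women`` independent life histories from age 40.

    Implements the cycle order used throughout the package: utility
    accrual on the state at the start of the year, then other-cause death,
    breast-cancer death, screening (if scheduled), symptomatic
    presentation, and onset/progression, each conditioned on the earlier
    events not firing.
    """
    if n_women < 1:
        raise ValidationError("need at least one woman")
    rng = np.random.default_rng(seed)

    rr_override = None
    if not strategy.is_screening and not params.rr_comparator_applies:
        rr_override = 1.0
    uptake = strategy.treatment_uptake
    v = 1.0 / (1.0 + params.discount_rate)
    util = utility_vector(params)
    sym = params.symptom_array()
    fatal = params.fatality_array()
    prog = params.progression_array()
    f_iv = params.stage_iv_fatality_untreated
    c_quest = params.costs["questionnaire"].baseline
    c_screen = params.costs["screening"].baseline
    c_biopsy = params.costs["biopsy"].baseline
    c_treat = params.treatment_cost_array()
    disut_fp = (params.disutility_fp.baseline
                * params.fp_disutility_duration_years)

    # per-state lookup vectors for vectorised sampling
    bc_death_p = np.zeros(len(S))
    bc_death_p[S.PRE_IV] = f_iv
    bc_death_p[S.DIAG_IV] = f_iv
    for stage, st in enumerate(TREATED_BY_STAGE):
        bc_death_p[st] = fatal[stage]
    sym_p = np.zeros(len(S))
    prog_p = np.zeros(len(S))
    next_state = np.arange(len(S))
    for stage, st in enumerate(PRECLINICAL_INVASIVE):
        sym_p[st] = sym[stage]
        if stage < 3:
            prog_p[st] = prog[stage]
            next_state[st] = PRECLINICAL_INVASIVE[stage + 1]
    for stage, st in enumerate(DIAG_BY_STAGE):
        if stage < 3:
            prog_p[st] = prog[stage]
            next_state[st] = DIAG_BY_STAGE[stage + 1]
    treated_for = np.arange(len(S))
    diag_for = np.arange(len(S))
    for stage, st in enumerate(PRECLINICAL_INVASIVE):
        treated_for[st] = TREATED_BY_STAGE[stage]
        diag_for[st] = DIAG_BY_STAGE[stage]
    treat_cost_of = np.zeros(len(S))
    treat_cost_of[S.DCIS] = c_treat[0]
    for stage, st in enumerate(PRECLINICAL_INVASIVE):
        treat_cost_of[st] = c_treat[1 + stage]

    n = int(n_women)
    state = np.full(n, int(S.HEALTHY), dtype=np.int64)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    n_screen_det = 0
    n_sym_det = 0
    n_onsets = 0
    n_dcis_det = 0
    n_fp = 0

    preclin_mask = np.zeros(len(S), dtype=bool)
    preclin_mask[list(PRECLINICAL_INVASIVE)] = True
    undiag_mask = np.zeros(len(S), dtype=bool)
    undiag_mask[[S.HEALTHY, S.DCIS, *PRECLINICAL_INVASIVE]] = True

    for t, age in enumerate(range(AGE_MIN, AGE_MAX + 1)):
        dt = v ** t
        alive = state < S.BC_DEATH
        qaly += dt * util[state]

        # 1: other-cause death
        q_oc = life_table.q_at(age)
        u = rng.random(n)
        state[alive & (u < q_oc)] = S.OTHER_DEATH
        alive = state < S.BC_DEATH

        # 2: breast-cancer death
        u = rng.random(n)
        state[alive & (u < bc_death_p[state])] = S.BC_DEATH
        alive = state < S.BC_DEATH

        # 3: screening round
        if strategy.schedules(age):
            perf = test_characteristics(age, strategy, params)
            sens, spec = perf
            att = alive & undiag_mask[state]
            cost[att] += dt * (c_quest + c_screen)
            u = rng.random(n)
            fp = att & (state == S.HEALTHY) & (u < 1.0 - spec)
            cost[fp] += dt * c_biopsy
            qaly[fp] -= dt * disut_fp * util[S.HEALTHY]
            n_fp += int(fp.sum())
            det = att & (state != S.HEALTHY) & (u < sens)
            cost[det] += dt * c_biopsy
            u2 = rng.random(n)
            treat = det & (u2 < uptake)
            cost[treat] += dt * treat_cost_of[state[treat]]
            dcis_treat = treat & (state == S.DCIS)
            n_dcis_det += int(dcis_treat.sum())
            inv_det = det & preclin_mask[state]
            n_screen_det += int(inv_det.sum()) + int(dcis_treat.sum())
            state[dcis_treat] = S.TREATED_DCIS
            inv_treat = treat & preclin_mask[state]
            inv_decline = inv_det & ~treat
            state[inv_treat] = treated_for[state[inv_treat]]
            state[inv_decline] = diag_for[state[inv_decline]]

        # 4: symptomatic presentation
        u = rng.random(n)
        present = (state < S.BC_DEATH) & preclin_mask[state] \
            & (u < sym_p[state])
        n_sym_det += int(present.sum())
        u2 = rng.random(n)
        treat = present & (u2 < uptake)
        cost[treat] += dt * treat_cost_of[state[treat]]
        state[treat] = treated_for[state[treat]]
        decline = present & ~treat
        state[decline] = diag_for[state[decline]]

        # 5: onset and progression
        p_inv = onset_probability(age, params, "invasive", rr_override)
        p_dcis = onset_probability(age, params, "dcis", rr_override)
        p_dcis_inv = min(params.rr_dcis_to_invasive * p_inv, 1.0)
        u = rng.random(n)
        healthy = state == S.HEALTHY
        to_inv = healthy & (u < p_inv)
        to_dcis = healthy & ~to_inv & (u < p_inv + (1.0 - p_inv) * p_dcis)
        dcis_prog = (state == S.DCIS) & (u < p_dcis_inv)
        progress = preclin_mask[state] | np.isin(state, DIAG_BY_STAGE)
        progress &= u < prog_p[state]
        n_onsets += int(to_inv.sum()) + int(dcis_prog.sum())
        state[to_inv] = S.PRE_I
        state[to_dcis] = S.DCIS
        state[dcis_prog] = S.PRE_I
        state[progress] = next_state[state[progress]]

    scale = 1000.0 / n
    counts = {
        "incident_cases": (n_screen_det + n_sym_det) * scale,
        "screen_detected": n_screen_det * scale,
        "symptom_detected": n_sym_det * scale,
        "invasive_onsets": n_onsets * scale,
        "dcis_detected": n_dcis_det * scale,
        "bc_deaths": float(np.sum(state == S.BC_DEATH)) * scale,
        "false_positive_episodes": n_fp * scale,
    }
    return MicrosimResult(
        n_women=n, seed=seed, strategy=strategy.name,
        mean_cost=float(cost.mean()), mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)),
        counts_per_1000=counts,
    )


def synthetic_life_table(level: float = 9e-4, slope: float = 0.095,
                         age_range: tuple[int, int] = (AGE_MIN, AGE_MAX)
                         ) -> LifeTable:
    """Gompertz other-cause mortality: hazard level*exp(slope*(age-40)).

    Hazards convert to annual probabilities via q = 1 - exp(-h).  The
    defaults give a remaining life expectancy at age 40 of roughly 42-43
    years, the magnitude reported for urban Chinese women; this synthetic
    table stands in for a national female life table.
    """
    if level <= 0:
        raise ValidationError("Gompertz level must be positive")
    if slope < 0:
        raise ValidationError("Gompertz slope must be non-negative")
    lo, hi = age_range
    ages = np.arange(lo, hi + 1)
    hazard = level * np.exp(slope * (ages - 40.0))
    q = 1.0 - np.exp(-hazard)
    if np.any(q[:-1] >= 1.0):
        raise ValidationError(
            "Gompertz parameters produce certain death before the horizon")
    return LifeTable(start_age=int(lo), q=tuple(float(x) for x in q))


def random_parameter_set(seed: int) -> ModelParameters:
    """A valid random parameter set for property tests.

    Unranged probabilities are perturbed within +/-50% of baseline
    (clipped to [0, 1]); ranged parameters are redrawn uniformly inside
    their published (min, max), which keeps every invariant satisfied by
    construction.
    """
    rng = np.random.default_rng(seed)
    base = default_parameters()
    d = base.to_dict()

    def jitter(x: float, lo: float = 0.0, hi: float = 1.0) -> float:
        return float(np.clip(x * rng.uniform(0.5, 1.5), lo, hi))

    d["incidence_by_age"] = {b: jitter(x)
                             for b, x in d["incidence_by_age"].items()}
    d["dcis_ratio"] = jitter(d["dcis_ratio"], hi=5.0)
    d["rr_dcis_to_invasive"] = jitter(d["rr_dcis_to_invasive"], hi=10.0)
    d["rr_high_risk"] = float(rng.uniform(1.0, 3.0))
    d["progression"] = {k: jitter(x) for k, x in d["progression"].items()}
    d["symptom_prob"] = {k: jitter(x) for k, x in d["symptom_prob"].items()}
    d["fatality_treated"] = {k: jitter(x)
                             for k, x in d["fatality_treated"].items()}

    def redraw(node: dict) -> dict:
        return dict(node, baseline=float(rng.uniform(node["min"], node["max"])))

    for combo in d["test_perf"]:
        for metric in d["test_perf"][combo]:
            d["test_perf"][combo][metric] = redraw(d["test_perf"][combo][metric])
    d["utility"] = {s: redraw(x) for s, x in d["utility"].items()}
    d["disutility_fp"] = redraw(d["disutility_fp"])
    for key in ("questionnaire", "screening", "biopsy"):
        d["costs"][key] = redraw(d["costs"][key])
    d["costs"]["treatment"] = {k: redraw(x)
                               for k, x in d["costs"]["treatment"].items()}
    return ModelParameters.from_dict(d)
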