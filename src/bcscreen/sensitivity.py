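"""One-way and probabilistic sensitivity analyses, CEAC, scenario grid.

One-way analysis re-evaluates the incremental cost-effectiveness ratio at
the published minimum and maximum of one parameter at a time, everything
else at baseline (a tornado table).  The probabilistic analysis draws all
ranged parameters jointly -- costs from gamma, utilities and the
false-positive disutility from log-normal, test sensitivity/specificity
from beta distributions -- and re-runs both arms per draw, yielding paired
incremental cost/effect samples; the cost-effectiveness acceptability
curve (CEAC) is the fraction of draws with positive net monetary benefit
across a willingness-to-pay grid.

Distribution fitting pins the mean to the baseline value and fits the
single remaining spread parameter so that the (2.5th, 97.5th) percentiles
match the published (min, max) in least squares.  Parameters without a
published range (transition probabilities, incidence) are held fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import run_cohort
from .economics import CeComparison, compare
from .errors import ConfigurationError, DomainError, FitError, ValidationError
from .parameters import (LifeTable, ModelParameters, Ranged, Strategy,
                         no_screening, strategy_by_name)

#: Distribution family per parameter group, as used in the analysis plan.
FAMILY_BY_GROUP = {"costs": "gamma", "utility": "log-normal",
                   "disutility_fp": "log-normal", "test_perf": "beta"}


def ranged_parameter_paths(params: ModelParameters) -> list[str]:
    """Dot-paths of every parameter carrying a published (min, max) range."""
    paths: list[str] = []
    for combo, perf in params.test_perf.items():
        for metric in ("sensitivity", "specificity"):
            if perf[metric].has_range:
                paths.append(f"test_perf.{combo}.{metric}")
    for stage, r in params.utility.items():
        if r.has_range:
            paths.append(f"utility.{stage}")
    if params.disutility_fp.has_range:
        paths.append("disutility_fp")
    for key in ("questionnaire", "screening", "biopsy"):
        if params.costs[key].has_range:
            paths.append(f"costs.{key}")
    for key, r in params.costs["treatment"].items():
        if r.has_range:
            paths.append(f"costs.treatment.{key}")
    return sorted(paths)


def _ranged_at(params: ModelParameters, path: str) -> Ranged:
    node = params.get_value(path)
    if not (isinstance(node, Mapping) and "baseline" in node):
        raise ConfigurationError(f"parameter {path!r} has no published range")
    r = Ranged.from_value(node, path)
    if not r.has_range:
        raise ConfigurationError(f"parameter {path!r} has no published range")
    return r


# ---------------------------------------------------------------------------
# Distribution fitting


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one uncertain parameter."""

    path: str
    family: str                      # 'gamma' | 'log-normal' | 'beta' | 'point'
    params: tuple[float, ...]
    baseline: float
    bounds: tuple[float, float] | None = None   # clip bounds for draws

    def mean(self) -> float:
        return self.baseline

    def _frozen(self):
        if self.family == "gamma":
            k, theta = self.params
            return stats.gamma(a=k, scale=theta)
        if self.family == "log-normal":
            mu, sigma = self.params
            return stats.lognorm(s=sigma, scale=np.exp(mu))
        if self.family == "beta":
            a, b = self.params
            return stats.beta(a=a, b=b)
        raise FitError(f"no frozen form for family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "point":
            return np.full(size, self.baseline)
        draws = self._frozen().rvs(size=size, random_state=rng)
        if self.bounds is not None:
            draws = np.clip(draws, *self.bounds)
        return draws

    def quantiles(self, q=(0.025, 0.975)) -> tuple[float, ...]:
        if self.family == "point":
            return tuple(self.baseline for _ in q)
        return tuple(float(self._frozen().ppf(x)) for x in q)


def _fit_spread(make_dist, lo: float, hi: float, log_bounds: tuple[float, float]
                ) -> float:
    """Fit a single log-spread parameter to the central 95% interval."""

    def sse(log_s: float) -> float:
        d = make_dist(np.exp(log_s))
        q = d.ppf([0.025, 0.975])
        return float((q[0] - lo) ** 2 + (q[1] - hi) ** 2)

    res = optimize.minimize_scalar(sse, bounds=log_bounds, method="bounded",
                                   options={"xatol": 1e-10})
    return float(np.exp(res.x))


def fit_distribution(baseline: float, minimum: float, maximum: float,
                     family: str, path: str = "") -> DistributionSpec:
    """Fit a gamma / log-normal / beta distribution with mean ``baseline``
    and its central 95% interval matched to (minimum, maximum)."""
    if not (minimum <= baseline <= maximum):
        raise ValidationError(
            f"{path or 'parameter'}: need min <= baseline <= max, got "
            f"({minimum}, {baseline}, {maximum})")
    if minimum == baseline == maximum:
        return DistributionSpec(path, "point", (), baseline)

    if family == "gamma":
        if baseline <= 0:
            raise FitError(f"{path}: gamma requires a positive baseline")
        # mean = k*theta pinned; spread parameter is 1/sqrt(k)
        def make(s):
            k = 1.0 / s ** 2
            return stats.gamma(a=k, scale=baseline / k)
        spread = _fit_spread(make, minimum, maximum, (-8.0, 2.0))
        k = 1.0 / spread ** 2
        spec = DistributionSpec(path, "gamma", (k, baseline / k), baseline,
                                bounds=(0.0, np.inf))
    elif family == "log-normal":
        if baseline <= 0:
            raise FitError(f"{path}: log-normal requires a positive baseline")
        # mean = exp(mu + sigma^2/2) pinned; fit sigma
        def make(sigma):
            mu = np.log(baseline) - sigma ** 2 / 2.0
            return stats.lognorm(s=sigma, scale=np.exp(mu))
        sigma = _fit_spread(make, minimum, maximum, (-8.0, 1.5))
        spec = DistributionSpec(path, "log-normal",
                                (float(np.log(baseline) - sigma ** 2 / 2.0),
                                 sigma), baseline, bounds=(0.0, np.inf))
    elif family == "beta":
        if not (0.0 < baseline < 1.0):
            raise FitError(f"{path}: beta requires a baseline in (0, 1)")
        # mean = a/(a+b) pinned; fit the concentration a+b
        def make(c):
            return stats.beta(a=baseline * c, b=(1.0 - baseline) * c)
        c = _fit_spread(make, minimum, maximum, (0.0, 18.0))
        spec = DistributionSpec(path, "beta",
                                (baseline * c, (1.0 - baseline) * c),
                                baseline, bounds=(0.0, 1.0))
    else:
        raise FitError(f"unknown distribution family {family!r}")

    q_lo, q_hi = spec.quantiles()
    width = maximum - minimum
    if width > 0 and (abs(q_lo - minimum) + abs(q_hi - maximum)) > width:
        raise FitError(
            f"{path or family}: cannot match mean {baseline} with 95% interval "
            f"({minimum}, {maximum}); achieved ({q_lo:.6g}, {q_hi:.6g})",
            achieved_quantiles=(q_lo, q_hi))
    return spec


def _family_for(path: str) -> str:
    group = path.split(".", 1)[0]
    return FAMILY_BY_GROUP[group]


def fit_all_distributions(params: ModelParameters) -> dict[str, DistributionSpec]:
    specs = {}
    for path in ranged_parameter_paths(params):
        r = _ranged_at(params, path)
        fam = _family_for(path)
        spec = fit_distribution(r.baseline, r.low, r.high, fam, path=path)
        if path.startswith(("utility.", "disutility_fp")):
            spec = DistributionSpec(spec.path, spec.family, spec.params,
                                    spec.baseline, bounds=(0.0, 1.0))
        specs[path] = spec
    return specs


# ---------------------------------------------------------------------------
# One-way (tornado) analysis


def _icer_for(params: ModelParameters, strategy: Strategy,
              comparator: Strategy, life_table: LifeTable) -> CeComparison:
    res_i = run_cohort(strategy, params, life_table)
    res_c = run_cohort(comparator, params, life_table)
    return compare(res_i, res_c, params.wtp_threshold)


def one_way(param_path: str, lo: float, hi: float, strategy: Strategy,
            comparator: Strategy, params: ModelParameters,
            life_table: LifeTable) -> tuple[float | None, float | None]:
    """ICER with one parameter at its minimum, then at its maximum."""
    _ranged_at(params, param_path)   # unsupported-parameter guard
    icers = []
    for value in (lo, hi):
        cmp_ = _icer_for(params.with_value(param_path, float(value)),
                         strategy, comparator, life_table)
        icers.append(cmp_.icer)
    return icers[0], icers[1]


def tornado(strategy: Strategy, comparator: Strategy,
            params: ModelParameters, life_table: LifeTable) -> pd.DataFrame:
    """One-way ICERs over every ranged parameter, sorted by ICER span."""
    base = _icer_for(params, strategy, comparator, life_table).icer
    rows = []
    for path in ranged_parameter_paths(params):
        r = _ranged_at(params, path)
        icer_lo, icer_hi = one_way(path, r.low, r.high, strategy, comparator,
                                   params, life_table)
        rows.append({"parameter": path, "low": r.low, "high": r.high,
                     "icer_at_low": icer_lo, "icer_at_high": icer_hi,
                     "icer_baseline": base,
                     "span": abs((icer_hi or np.nan) - (icer_lo or np.nan))})
    return pd.DataFrame(rows).sort_values("span", ascending=False,
                                          ignore_index=True)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass
class PsaDraws:
    """Paired incremental cost/effect samples with their provenance."""

    incremental_cost: np.ndarray
    incremental_qaly: np.ndarray
    seed: int
    distribution_specs: dict[str, DistributionSpec]
    parameter_draws: pd.DataFrame
    strategy: str
    comparator: str

    @property
    def n(self) -> int:
        return len(self.incremental_cost)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"incremental_cost": self.incremental_cost,
                             "incremental_qaly": self.incremental_qaly})


def run_psa(n: int, seed: int, strategy: Strategy, comparator: Strategy,
            params: ModelParameters, life_table: LifeTable,
            specs: dict[str, DistributionSpec] | None = None) -> PsaDraws:
    """Joint Monte-Carlo over all ranged parameters; two cohort runs per draw.

    A single seeded generator drives the draws, with parameters sampled in
    sorted-path order so results are reproducible across runs and
    platforms.
    """
    if n < 1:
        raise ValidationError("PSA needs at least one draw")
    if specs is None:
        specs = fit_all_distributions(params)
    rng = np.random.default_rng(seed)
    draws = {path: specs[path].sample(rng, n) for path in sorted(specs)}
    draw_df = pd.DataFrame(draws)

    d_cost = np.empty(n)
    d_qaly = np.empty(n)
    for i in range(n):
        p_i = params
        d = p_i.to_dict()
        for path, values in draws.items():
            _set_in_dict(d, path, float(values[i]))
        p_i = ModelParameters.from_dict(d)
        cmp_ = _icer_for(p_i, strategy, comparator, life_table)
        d_cost[i] = cmp_.incremental_cost
        d_qaly[i] = cmp_.incremental_qaly
    return PsaDraws(incremental_cost=d_cost, incremental_qaly=d_qaly,
                    seed=seed, distribution_specs=specs,
                    parameter_draws=draw_df, strategy=strategy.name,
                    comparator=comparator.name)


def _set_in_dict(d: dict, path: str, value: float) -> None:
    parts = path.split(".")
    node = d
    for part in parts[:-1]:
        node = node[part]
    leaf = parts[-1]
    old = node[leaf]
    if isinstance(old, Mapping) and "baseline" in old:
        # drop the published range: it described the baseline, and a draw
        # may legitimately fall outside it; explicit nulls stop the
        # defaults from re-injecting it on reload
        node[leaf] = {"baseline": value, "min": None, "max": None}
    else:
        node[leaf] = value


def ceac(draws: PsaDraws, wtp_grid: Iterable[float]) -> pd.DataFrame:
    """P(cost-effective) = fraction of draws with NMB > 0, per WTP value."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise DomainError("CEAC needs a non-empty willingness-to-pay grid")
    probs = [float(np.mean(w * draws.incremental_qaly
                           - draws.incremental_cost > 0)) for w in grid]
    return pd.DataFrame({"wtp": grid, "probability_cost_effective": probs})


# ---------------------------------------------------------------------------
# Scenario grid


def run_scenarios(params: ModelParameters, life_table: LifeTable
                  ) -> pd.DataFrame:
    """The programme's scenario grid versus no screening.

    Screening every 1, 3 and 5 years; annual screening with 70% treatment
    uptake; and, when mammography-alone test performance is supplied in the
    configuration, the 45-69 mammography-alone variants.  Rows mirror the
    published comparison table: per-arm discounted cost and QALY,
    increments, and ICER.
    """
    comparator = no_screening()
    base = run_cohort(comparator, params, life_table)

    def row(strategy: Strategy, scenario: str) -> dict:
        res = run_cohort(strategy, params, life_table)
        cmp_ = compare(res, base, params.wtp_threshold)
        return {"scenario": scenario, "strategy": strategy.name,
                "comparator": "none",
                "discounted_cost": res.discounted_cost,
                "discounted_qaly": res.discounted_qaly,
                "incremental_cost": cmp_.incremental_cost,
                "incremental_qaly": cmp_.incremental_qaly,
                "icer": cmp_.icer, "cost_effective": cmp_.cost_effective}

    rows = [
        {"scenario": "baseline", "strategy": "none", "comparator": "",
         "discounted_cost": base.discounted_cost,
         "discounted_qaly": base.discounted_qaly,
         "incremental_cost": np.nan, "incremental_qaly": np.nan,
         "icer": np.nan, "cost_effective": np.nan},
        row(strategy_by_name("annual"), "baseline"),
        row(strategy_by_name("q3"), "interval"),
        row(strategy_by_name("q5"), "interval"),
        row(Strategy(name="annual_70pct_uptake", screening_interval_years=1,
                     treatment_uptake=0.7), "treatment access"),
    ]

    if "mammography_alone" in params.test_perf:
        for name, interval in (("annual", 1), ("q3", 3), ("q5", 5)):
            strat = Strategy(
                name=f"mammography_alone_{name}",
                screening_interval_years=interval,
                modality_by_age_band=(
                    ((40, 44), "ultrasound_then_mammography"),
                    ((45, 69), "mammography_alone")),
            )
            rows.append(row(strat, "mammography alone"))
    else:
        warnings.warn(
            "mammography-alone test performance not configured; skipping the "
            "mammography-alone scenario rows", stacklevel=2)
    return pd.DataFrame(rows)
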