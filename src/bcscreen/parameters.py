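"""Model parameters, screening strategies and life tables.

All epidemiological, test-performance, utility and cost inputs of the model
live here.  Baseline values describe the 2012 risk-based breast-cancer
screening programme in urban China: stage-progression probabilities, the
calibrated stage-specific symptom probabilities, post-treatment fatality
rates, sensitivity/specificity of the ultrasound/mammography combinations
used by age band, EQ-5D utility scores by stage, and 2014 US$ costs for the
questionnaire, a screening round, biopsy and one-time treatment by stage.

Parameters are plain frozen dataclasses serialisable to/from YAML.  Every
uncertain quantity with a published range is stored as a :class:`Ranged`
triple (baseline, low, high); quantities without a range are plain floats
and are held fixed in sensitivity analyses.
"""

from __future__ import annotations

import copy
import io
import math
import os
from dataclasses import dataclass
from typing import IO, Any, Mapping

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError, ValidationError

AGE_MIN = 40
#: Oldest modelled age; the horizon is absorbing at this age.
AGE_MAX = 100

AGE_BAND_LABELS = (
    "40-44", "45-49", "50-54", "55-59", "60-64",
    "65-69", "70-74", "75-79", "80-84", "85+",
)

STAGES = ("stage_i", "stage_ii", "stage_iii", "stage_iv")
PROGRESSION_KEYS = ("stage_i_to_ii", "stage_ii_to_iii", "stage_iii_to_iv",
                    "stage_iv_to_death")
TREATMENT_KEYS = ("dcis",) + STAGES

ULTRASOUND_THEN_MAMMO = "ultrasound_then_mammography"
ULTRASOUND_PLUS_MAMMO = "ultrasound_plus_mammography"


def _band_for_age(age: int) -> str:
    if age < AGE_MIN:
        raise DomainError(f"age {age} is below the model entry age {AGE_MIN}")
    if age > AGE_MAX:
        raise DomainError(f"age {age} is above the model horizon {AGE_MAX}")
    if age >= 85:
        return "85+"
    lo = 40 + 5 * ((int(age) - 40) // 5)
    return f"{lo}-{lo + 4}"


# ---------------------------------------------------------------------------
# Ranged values


@dataclass(frozen=True)
class Ranged:
    """A baseline value with an optional published (low, high) range."""

    baseline: float
    low: float | None = None
    high: float | None = None

    @property
    def has_range(self) -> bool:
        return self.low is not None and self.high is not None

    def validate(self, path: str, lo_bound: float, hi_bound: float) -> None:
        vals = [("baseline", self.baseline)]
        if self.low is not None:
            vals.append(("min", self.low))
        if self.high is not None:
            vals.append(("max", self.high))
        for name, v in vals:
            if not (lo_bound <= v <= hi_bound):
                raise ValidationError(
                    f"{path}.{name} = {v} outside [{lo_bound}, {hi_bound}]")
        if self.has_range and not (self.low <= self.baseline <= self.high):
            raise ValidationError(
                f"{path}: requires min <= baseline <= max, got "
                f"({self.low}, {self.baseline}, {self.high})")

    def to_dict(self) -> dict | float:
        if self.low is None and self.high is None:
            return float(self.baseline)
        return {"baseline": float(self.baseline), "min": float(self.low),
                "max": float(self.high)}

    @classmethod
    def from_value(cls, value: Any, path: str) -> "Ranged":
        if isinstance(value, Ranged):
            return value
        if isinstance(value, (int, float)):
            return cls(float(value))
        if isinstance(value, Mapping):
            try:
                base = float(value["baseline"])
            except KeyError as exc:
                raise ConfigurationError(f"missing key {path}.baseline") from exc
            low = value.get("min")
            high = value.get("max")
            return cls(base,
                       None if low is None else float(low),
                       None if high is None else float(high))
        raise ConfigurationError(f"{path}: cannot interpret {value!r} as a value")


# ---------------------------------------------------------------------------
# Baseline parameter set (2014 US$; annual probabilities)

_DEFAULTS: dict[str, Any] = {
    "incidence_by_age": {
        "40-44": 0.0006100,
        "45-49": 0.0010056,
        "50-54": 0.0011650,
        "55-59": 0.0011179,
        "60-64": 0.0010458,
        "65-69": 0.0009782,
        "70-74": 0.0009912,
        "75-79": 0.0009067,
        "80-84": 0.0007803,
        "85+": 0.0006430,
    },
    "dcis_ratio": 0.12,
    "rr_dcis_to_invasive": 2.02,
    "rr_high_risk": 2.0,
    "comparator_high_risk": True,
    "progression": {
        "stage_i_to_ii": 0.06,
        "stage_ii_to_iii": 0.11,
        "stage_iii_to_iv": 0.15,
        "stage_iv_to_death": 0.23,
    },
    "symptom_prob": {
        "stage_i": 0.004,
        "stage_ii": 0.014,
        "stage_iii": 0.380,
        "stage_iv": 0.980,
    },
    "fatality_treated": {
        "stage_i": 0.006,
        "stage_ii": 0.042,
        "stage_iii": 0.093,
        "stage_iv": 0.275,
    },
    "test_perf": {
        ULTRASOUND_THEN_MAMMO: {
            "sensitivity": {"baseline": 0.848, "min": 0.681, "max": 0.949},
            "specificity": {"baseline": 0.994, "min": 0.990, "max": 0.996},
        },
        ULTRASOUND_PLUS_MAMMO: {
            "sensitivity": {"baseline": 0.939, "min": 0.798, "max": 0.993},
            "specificity": {"baseline": 0.980, "min": 0.975, "max": 0.985},
        },
    },
    "utility": {
        "stage_i": {"baseline": 0.79, "min": 0.77, "max": 0.80},
        "stage_ii": {"baseline": 0.79, "min": 0.78, "max": 0.80},
        "stage_iii": {"baseline": 0.77, "min": 0.76, "max": 0.79},
        "stage_iv": {"baseline": 0.69, "min": 0.65, "max": 0.72},
    },
    "disutility_fp": {"baseline": 0.25, "min": 0.11, "max": 0.34},
    # duration of the false-positive disutility episode, in years
    # (positive screen to biopsy resolution; ~5 weeks)
    "fp_disutility_duration_years": 5.0 / 52.0,
    "costs": {
        "questionnaire": {"baseline": 1.6, "min": 1.1, "max": 2.1},
        "screening": {"baseline": 85.5, "min": 59.8, "max": 111.1},
        "biopsy": {"baseline": 45.6, "min": 31.0, "max": 59.3},
        "treatment": {
            "dcis": {"baseline": 2435.0, "min": 1705.0, "max": 3166.0},
            "stage_i": {"baseline": 10067.0, "min": 7047.0, "max": 13087.0},
            "stage_ii": {"baseline": 11068.0, "min": 7748.0, "max": 14388.0},
            "stage_iii": {"baseline": 12867.0, "min": 9007.0, "max": 16727.0},
            "stage_iv": {"baseline": 17766.0, "min": 12436.0, "max": 23096.0},
        },
    },
    "discount_rate": 0.03,
    "wtp_threshold": 23050.0,
    "preclinical_stage_utility": True,
    "half_cycle_correction": False,
}


@dataclass(frozen=True)
class ModelParameters:
    incidence_by_age: Mapping[str, float]
    dcis_ratio: float
    rr_dcis_to_invasive: float
    rr_high_risk: float
    progression: Mapping[str, float]
    symptom_prob: Mapping[str, float]
    fatality_treated: Mapping[str, float]
    test_perf: Mapping[str, Mapping[str, Ranged]]
    utility: Mapping[str, Ranged]
    disutility_fp: Ranged
    fp_disutility_duration_years: float
    costs: Mapping[str, Any]
    discount_rate: float = 0.03
    wtp_threshold: float = 23050.0
    rr_comparator_applies: bool = True
    preclinical_stage_utility: bool = True
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        self._validate()

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        missing = [b for b in AGE_BAND_LABELS if b not in self.incidence_by_age]
        if missing:
            raise ConfigurationError(
                f"missing key incidence_by_age.{missing[0]}")
        for band, p in self.incidence_by_age.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(
                    f"incidence_by_age.{band} = {p} outside [0, 1]")
        if not (0.0 <= self.dcis_ratio):
            raise ValidationError("dcis_ratio must be >= 0")
        if self.rr_dcis_to_invasive < 0:
            raise ValidationError("rr_dcis_to_invasive must be >= 0")
        if self.rr_high_risk <= 0:
            raise ValidationError("rr_high_risk must be > 0")
        if self.discount_rate < 0:
            raise ValidationError("discount_rate must be >= 0")
        if self.wtp_threshold < 0:
            raise ValidationError("wtp_threshold must be >= 0")
        for key in PROGRESSION_KEYS:
            if key not in self.progression:
                raise ConfigurationError(f"missing key progression.{key}")
            p = self.progression[key]
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"progression.{key} = {p} outside [0, 1]")
        for group_name, group in (("symptom_prob", self.symptom_prob),
                                  ("fatality_treated", self.fatality_treated)):
            for stage in STAGES:
                if stage not in group:
                    raise ConfigurationError(f"missing key {group_name}.{stage}")
                p = group[stage]
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(
                        f"{group_name}.{stage} = {p} outside [0, 1]")
        for combo, perf in self.test_perf.items():
            for metric in ("sensitivity", "specificity"):
                if metric not in perf:
                    raise ConfigurationError(
                        f"missing key test_perf.{combo}.{metric}")
                perf[metric].validate(f"test_perf.{combo}.{metric}", 0.0, 1.0)
        for stage in STAGES:
            if stage not in self.utility:
                raise ConfigurationError(f"missing key utility.{stage}")
            self.utility[stage].validate(f"utility.{stage}", 0.0, 1.0)
        self.disutility_fp.validate("disutility_fp", 0.0, 1.0)
        if not (0.0 <= self.fp_disutility_duration_years <= 1.0):
            raise ValidationError(
                "fp_disutility_duration_years must lie in [0, 1]")
        for key in ("questionnaire", "screening", "biopsy"):
            if key not in self.costs:
                raise ConfigurationError(f"missing key costs.{key}")
            self.costs[key].validate(f"costs.{key}", 0.0, math.inf)
        treatment = self.costs.get("treatment")
        if treatment is None:
            raise ConfigurationError("missing key costs.treatment")
        for key in TREATMENT_KEYS:
            if key not in treatment:
                raise ConfigurationError(f"missing key costs.treatment.{key}")
            treatment[key].validate(f"costs.treatment.{key}", 0.0, math.inf)

    # -- array accessors used by the engines -------------------------------

    def incidence_for_age(self, age: int) -> float:
        return float(self.incidence_by_age[_band_for_age(age)])

    def progression_array(self) -> np.ndarray:
        """Stage I->II, II->III, III->IV annual probabilities."""
        return np.array([self.progression[k] for k in PROGRESSION_KEYS[:3]])

    @property
    def stage_iv_fatality_untreated(self) -> float:
        return float(self.progression["stage_iv_to_death"])

    def symptom_array(self) -> np.ndarray:
        return np.array([self.symptom_prob[s] for s in STAGES])

    def fatality_array(self) -> np.ndarray:
        return np.array([self.fatality_treated[s] for s in STAGES])

    def utility_array(self) -> np.ndarray:
        return np.array([self.utility[s].baseline for s in STAGES])

    def treatment_cost_array(self) -> np.ndarray:
        """One-time treatment cost for DCIS, stages I-IV."""
        t = self.costs["treatment"]
        return np.array([t[k].baseline for k in TREATMENT_KEYS])

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "incidence_by_age": {b: float(v)
                                 for b, v in self.incidence_by_age.items()},
            "dcis_ratio": float(self.dcis_ratio),
            "rr_dcis_to_invasive": float(self.rr_dcis_to_invasive),
            "rr_high_risk": float(self.rr_high_risk),
            "comparator_high_risk": bool(self.rr_comparator_applies),
            "progression": {k: float(v) for k, v in self.progression.items()},
            "symptom_prob": {k: float(v) for k, v in self.symptom_prob.items()},
            "fatality_treated": {k: float(v)
                                 for k, v in self.fatality_treated.items()},
            "test_perf": {combo: {m: r.to_dict() for m, r in perf.items()}
                          for combo, perf in self.test_perf.items()},
            "utility": {s: r.to_dict() for s, r in self.utility.items()},
            "disutility_fp": self.disutility_fp.to_dict(),
            "fp_disutility_duration_years":
                float(self.fp_disutility_duration_years),
            "costs": {
                "questionnaire": self.costs["questionnaire"].to_dict(),
                "screening": self.costs["screening"].to_dict(),
                "biopsy": self.costs["biopsy"].to_dict(),
                "treatment": {k: r.to_dict()
                              for k, r in self.costs["treatment"].items()},
            },
            "discount_rate": float(self.discount_rate),
            "wtp_threshold": float(self.wtp_threshold),
            "preclinical_stage_utility": bool(self.preclinical_stage_utility),
            "half_cycle_correction": bool(self.half_cycle_correction),
        }

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "ModelParameters":
        d = _deep_merge(copy.deepcopy(_DEFAULTS), raw)
        known = set(_DEFAULTS)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration key(s): "
                                     f"{', '.join(sorted(unknown))}")
        for key in known:
            if d.get(key) is None:
                raise ConfigurationError(f"missing key {key}")

        def ranged(node: Any, path: str) -> Ranged:
            if node is None:
                raise ConfigurationError(f"missing key {path}")
            return Ranged.from_value(node, path)

        test_perf = {
            combo: {m: ranged(perf.get(m), f"test_perf.{combo}.{m}")
                    for m in ("sensitivity", "specificity")}
            for combo, perf in d["test_perf"].items()
        }
        utility = {s: ranged(d["utility"].get(s), f"utility.{s}")
                   for s in d["utility"]}
        costs = {
            "questionnaire": ranged(d["costs"].get("questionnaire"),
                                    "costs.questionnaire"),
            "screening": ranged(d["costs"].get("screening"), "costs.screening"),
            "biopsy": ranged(d["costs"].get("biopsy"), "costs.biopsy"),
            "treatment": {k: ranged(d["costs"]["treatment"].get(k),
                                    f"costs.treatment.{k}")
                          for k in d["costs"]["treatment"]},
        }
        return cls(
            incidence_by_age={b: float(v)
                              for b, v in d["incidence_by_age"].items()},
            dcis_ratio=float(d["dcis_ratio"]),
            rr_dcis_to_invasive=float(d["rr_dcis_to_invasive"]),
            rr_high_risk=float(d["rr_high_risk"]),
            progression={k: float(v) for k, v in d["progression"].items()},
            symptom_prob={k: float(v) for k, v in d["symptom_prob"].items()},
            fatality_treated={k: float(v)
                              for k, v in d["fatality_treated"].items()},
            test_perf=test_perf,
            utility=utility,
            disutility_fp=ranged(d["disutility_fp"], "disutility_fp"),
            fp_disutility_duration_years=float(
                d["fp_disutility_duration_years"]),
            costs=costs,
            discount_rate=float(d["discount_rate"]),
            wtp_threshold=float(d["wtp_threshold"]),
            rr_comparator_applies=bool(d["comparator_high_risk"]),
            preclinical_stage_utility=bool(d["preclinical_stage_utility"]),
            half_cycle_correction=bool(d["half_cycle_correction"]),
        )

    # -- generic path access (used by sensitivity analyses) ----------------

    def get_value(self, path: str) -> Any:
        node: Any = self.to_dict()
        for part in path.split("."):
            try:
                node = node[part]
            except (KeyError, TypeError) as exc:
                raise ConfigurationError(f"no parameter at path {path!r}") from exc
        return node

    def with_value(self, path: str, value: Any) -> "ModelParameters":
        """Return a copy with the (possibly nested) value at ``path`` replaced.

        When the target is a ranged value, a bare float replaces its baseline
        and drops an inconsistent range rather than failing validation.
        """
        d = self.to_dict()
        parts = path.split(".")
        node = d
        for part in parts[:-1]:
            try:
                node = node[part]
            except (KeyError, TypeError) as exc:
                raise ConfigurationError(f"no parameter at path {path!r}") from exc
        leaf = parts[-1]
        if leaf not in node:
            raise ConfigurationError(f"no parameter at path {path!r}")
        old = node[leaf]
        if isinstance(old, Mapping) and "baseline" in old \
                and isinstance(value, (int, float)):
            new = dict(old, baseline=float(value))
            if new.get("min") is not None and not (
                    new["min"] <= new["baseline"] <= new["max"]):
                # explicit nulls so defaults cannot re-inject the range
                new = {"baseline": float(value), "min": None, "max": None}
            node[leaf] = new
        else:
            node[leaf] = value
        return ModelParameters.from_dict(d)


def _is_ranged_leaf(node: Any) -> bool:
    return isinstance(node, Mapping) and "baseline" in node


def _deep_merge(base: dict, override: Mapping) -> dict:
    for key, value in override.items():
        if (key in base and isinstance(base[key], dict)
                and isinstance(value, Mapping)
                and not (_is_ranged_leaf(base[key]) or _is_ranged_leaf(value))):
            base[key] = _deep_merge(base[key], value)
        else:
            # ranged values merge atomically: overriding a baseline alone
            # must not inherit a (now inconsistent) default range
            base[key] = copy.deepcopy(value)
    return base


def load_parameters(source: str | os.PathLike | IO[str] | Mapping | None = None
                    ) -> ModelParameters:
    """Load and validate a parameter set from YAML (path, stream or mapping).

    Keys omitted from the document fall back to the programme's baseline
    values; ``None`` given the default config reproduces the baselines
    exactly.
    """
    if source is None:
        raw: Mapping = {}
    elif isinstance(source, Mapping):
        raw = source
    elif isinstance(source, (str, os.PathLike)):
        try:
            with open(source, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigurationError(f"cannot read config {source!r}: {exc}") \
                from exc
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config {source!r}: {exc}") \
                from exc
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        try:
            raw = yaml.safe_load(source.read()) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config stream: {exc}") from exc
    else:
        raise ConfigurationError(f"unsupported config source {type(source)}")
    if not isinstance(raw, Mapping):
        raise ConfigurationError("configuration document must be a mapping")
    return ModelParameters.from_dict(raw)


def serialize_parameters(params: ModelParameters) -> str:
    """YAML document that reproduces ``params`` under :func:`load_parameters`."""
    return yaml.safe_dump(params.to_dict(), sort_keys=False)


def default_parameters() -> ModelParameters:
    return ModelParameters.from_dict({})


def bundled_config_path() -> str:
    """Path of the packaged baseline parameter file."""
    return os.path.join(os.path.dirname(__file__), "data", "params_table1.yaml")


def onset_probability(age: int, params: ModelParameters,
                      lesion: str = "invasive",
                      rr_override: float | None = None) -> float:
    """Annual probability that a healthy high-risk woman develops a lesion.

    ``invasive``: age-band incidence scaled by the high-risk relative risk.
    ``dcis``: the invasive onset probability scaled by the in-situ/invasive
    incidence ratio.
    """
    rr = params.rr_high_risk if rr_override is None else rr_override
    p = params.incidence_for_age(age) * rr
    if lesion == "dcis":
        p *= params.dcis_ratio
    elif lesion != "invasive":
        raise DomainError(f"unknown lesion type {lesion!r}")
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Screening strategies


@dataclass(frozen=True)
class Strategy:
    """A screening policy: interval, eligible ages, modality by age band.

    ``screening_interval_years = 0`` means no screening.  The default
    modality map mirrors the programme: women aged 40-44 receive ultrasound
    with mammography triage; women aged 45-69 receive both ultrasound and
    mammography.
    """

    name: str
    screening_interval_years: int
    eligible_age_range: tuple[int, int] = (40, 69)
    modality_by_age_band: tuple[tuple[tuple[int, int], str], ...] = (
        ((40, 44), ULTRASOUND_THEN_MAMMO),
        ((45, 69), ULTRASOUND_PLUS_MAMMO),
    )
    treatment_uptake: float = 1.0

    def __post_init__(self) -> None:
        if self.screening_interval_years < 0:
            raise ValidationError("screening interval must be >= 0")
        if not (0.0 <= self.treatment_uptake <= 1.0):
            raise ValidationError("treatment_uptake must lie in [0, 1]")
        lo, hi = self.eligible_age_range
        if self.is_screening:
            bands = sorted(self.modality_by_age_band)
            if not bands:
                raise ValidationError("a screening strategy needs modality bands")
            expected = lo
            for (b_lo, b_hi), _combo in bands:
                if b_lo != expected or b_hi < b_lo:
                    raise ValidationError(
                        "modality bands must tile the eligible age range")
                expected = b_hi + 1
            if expected != hi + 1:
                raise ValidationError(
                    "modality bands must tile the eligible age range")

    @property
    def is_screening(self) -> bool:
        return self.screening_interval_years > 0

    def screening_ages(self) -> tuple[int, ...]:
        if not self.is_screening:
            return ()
        lo, hi = self.eligible_age_range
        return tuple(range(lo, hi + 1, self.screening_interval_years))

    def modality_for_age(self, age: int) -> str | None:
        """The modality combination for an eligible age; None if not screened."""
        if not self.is_screening:
            return None
        lo, hi = self.eligible_age_range
        if not (lo <= age <= hi):
            return None
        for (b_lo, b_hi), combo in self.modality_by_age_band:
            if b_lo <= age <= b_hi:
                return combo
        return None

    def schedules(self, age: int) -> bool:
        return age in self.screening_ages()


def no_screening() -> Strategy:
    return Strategy(name="none", screening_interval_years=0)


def strategy_by_name(name: str, treatment_uptake: float = 1.0) -> Strategy:
    """Named policies: none, annual, q3 (triennial), q5 (quinquennial)."""
    intervals = {"none": 0, "annual": 1, "q3": 3, "triennial": 3,
                 "q5": 5, "quinquennial": 5}
    if name not in intervals:
        raise ConfigurationError(
            f"unknown strategy {name!r}; expected one of {sorted(intervals)}")
    interval = intervals[name]
    if interval == 0:
        return Strategy(name="none", screening_interval_years=0,
                        treatment_uptake=treatment_uptake)
    return Strategy(name=name, screening_interval_years=interval,
                    treatment_uptake=treatment_uptake)


# ---------------------------------------------------------------------------
# Life table


@dataclass(frozen=True)
class LifeTable:
    """Annual probabilities of death from causes other than breast cancer.

    Indexed by integer age from ``start_age`` (40) through the model
    horizon.  The final modelled age is treated as absorbing by the cohort
    engine, so the table value there only affects nothing beyond the
    truncated tail.
    """

    start_age: int
    q: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.q) == 0:
            raise ValidationError("life table is empty")
        arr = np.asarray(self.q, dtype=float)
        if np.any((arr < 0) | (arr > 1)) or np.any(~np.isfinite(arr)):
            raise ValidationError("life-table probabilities must lie in [0, 1]")

    @property
    def max_age(self) -> int:
        return self.start_age + len(self.q) - 1

    def q_at(self, age: int) -> float:
        if not (self.start_age <= age <= self.max_age):
            raise DomainError(
                f"life table covers ages {self.start_age}-{self.max_age}, "
                f"not {age}")
        return self.q[age - self.start_age]

    def covers(self, lo: int, hi: int) -> bool:
        return self.start_age <= lo and hi <= self.max_age

    def survival_curve(self) -> np.ndarray:
        """S(t): probability of being alive at the start of cycle t."""
        arr = np.asarray(self.q, dtype=float)
        surv = np.ones(len(arr) + 1)
        surv[1:] = np.cumprod(1.0 - arr)
        return surv[:-1]

    def discounted_life_expectancy(self, rate: float) -> float:
        """Closed-form discounted life years from ``start_age``.

        Accrual convention matches the cohort engine: one (discounted) year
        is credited to everyone alive at the start of each annual cycle, up
        to and including the final modelled age.
        """
        t = np.arange(len(self.q))
        return float(np.sum(self.survival_curve() / (1.0 + rate) ** t))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"age": np.arange(self.start_age, self.max_age + 1),
                             "q_other_cause": np.asarray(self.q)})

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "LifeTable":
        ages = sorted(mapping)
        if ages != list(range(ages[0], ages[-1] + 1)):
            raise ValidationError("life table has gaps in its age coverage")
        return cls(start_age=ages[0], q=tuple(float(mapping[a]) for a in ages))

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "LifeTable":
        import pandas as pd

        try:
            df = pd.read_csv(path)
        except OSError as exc:
            raise ConfigurationError(f"cannot read life table {path!r}: {exc}") \
                from exc
        cols = {c.lower(): c for c in df.columns}
        if "age" not in cols or not ({"q", "q_other_cause"} & set(cols)):
            raise ConfigurationError(
                "life-table CSV needs columns 'age' and 'q' (or 'q_other_cause')")
        qcol = cols.get("q_other_cause", cols.get("q"))
        return cls.from_mapping({int(a): float(v)
                                 for a, v in zip(df[cols["age"]], df[qcol])})
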