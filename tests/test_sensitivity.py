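"""Distribution fitting, one-way analysis, PSA, CEAC and scenarios."""

import numpy as np
import pytest

from bcscreen import ceac, fit_distribution, one_way, run_psa, run_scenarios
from bcscreen.errors import (ConfigurationError, DomainError, FitError)
from bcscreen.sensitivity import (fit_all_distributions,
                                  ranged_parameter_paths, tornado)


class TestFitDistribution:
    def test_beta_mean_pinned_to_baseline(self):
        spec = fit_distribution(0.939, 0.798, 0.993, "beta")
        assert spec.mean() == pytest.approx(0.939, rel=0.01)
        lo, hi = spec.quantiles()
        assert 0.75 < lo < 0.90 and 0.95 < hi <= 1.0

    def test_gamma_mean_and_positive_support(self):
        spec = fit_distribution(85.5, 59.8, 111.1, "gamma")
        assert spec.mean() == pytest.approx(85.5)
        draws = spec.sample(np.random.default_rng(0), 20000)
        assert np.all(draws > 0)
        assert draws.mean() == pytest.approx(85.5, rel=0.02)
        lo, hi = spec.quantiles()
        assert lo == pytest.approx(59.8, rel=0.10)
        assert hi == pytest.approx(111.1, rel=0.10)

    def test_lognormal_fit(self):
        spec = fit_distribution(0.79, 0.77, 0.80, "log-normal")
        draws = spec.sample(np.random.default_rng(1), 20000)
        assert draws.mean() == pytest.approx(0.79, rel=0.005)

    def test_degenerate_range_gives_point_mass(self):
        spec = fit_distribution(5.0, 5.0, 5.0, "gamma")
        assert spec.family == "point"
        assert np.all(spec.sample(np.random.default_rng(0), 10) == 5.0)

    def test_inverted_range_rejected(self):
        with pytest.raises(Exception):
            fit_distribution(0.5, 0.6, 0.7, "beta")

    def test_unknown_family_rejected(self):
        with pytest.raises(FitError):
            fit_distribution(1.0, 0.5, 1.5, "weibull")

    def test_all_ranged_parameters_get_specs(self, params):
        specs = fit_all_distributions(params)
        paths = ranged_parameter_paths(params)
        assert set(specs) == set(paths)
        assert "costs.treatment.stage_iv" in specs
        assert specs["utility.stage_iv"].family == "log-normal"
        assert specs["costs.biopsy"].family == "gamma"
        assert specs[
            "test_perf.ultrasound_then_mammography.sensitivity"].family == \
            "beta"


class TestOneWay:
    def test_degenerate_range_returns_baseline_icer(self, params, life_table,
                                                    annual, none_strategy):
        from bcscreen import compare, run_cohort
        base_icer = compare(run_cohort(annual, params, life_table),
                            run_cohort(none_strategy, params, life_table),
                            params.wtp_threshold).icer
        lo, hi = one_way("costs.screening", 85.5, 85.5, annual,
                         none_strategy, params, life_table)
        assert lo == pytest.approx(base_icer)
        assert hi == pytest.approx(base_icer)

    def test_icer_monotone_in_screening_cost(self, params, life_table,
                                             annual, none_strategy):
        lo, hi = one_way("costs.screening", 59.8, 111.1, annual,
                         none_strategy, params, life_table)
        assert lo < hi

    def test_parameter_without_range_rejected(self, params, life_table,
                                              annual, none_strategy):
        with pytest.raises(ConfigurationError, match="range"):
            one_way("progression.stage_i_to_ii", 0.05, 0.07, annual,
                    none_strategy, params, life_table)

    def test_tornado_covers_all_ranged_parameters(self, params, life_table,
                                                  annual, none_strategy):
        # tiny surrogate: restrict to two parameters via direct calls
        df = tornado(annual, none_strategy, params, life_table)
        assert set(df["parameter"]) == set(ranged_parameter_paths(params))
        assert (df["span"].values[:-1] >= df["span"].values[1:]).all()


class TestPsa:
    def test_same_seed_reproduces_draws(self, params, life_table, annual,
                                        none_strategy):
        a = run_psa(12, 7, annual, none_strategy, params, life_table)
        b = run_psa(12, 7, annual, none_strategy, params, life_table)
        assert np.array_equal(a.incremental_cost, b.incremental_cost)
        assert np.array_equal(a.incremental_qaly, b.incremental_qaly)
        assert a.parameter_draws.equals(b.parameter_draws)

    def test_different_seeds_differ(self, params, life_table, annual,
                                    none_strategy):
        a = run_psa(6, 1, annual, none_strategy, params, life_table)
        b = run_psa(6, 2, annual, none_strategy, params, life_table)
        assert not np.array_equal(a.incremental_cost, b.incremental_cost)

    def test_draw_marginals_match_their_specs(self, params):
        specs = fit_all_distributions(params)
        rng = np.random.default_rng(3)
        for path in ("costs.screening", "utility.stage_ii",
                     "test_perf.ultrasound_plus_mammography.specificity"):
            draws = specs[path].sample(rng, 10000)
            assert draws.mean() == pytest.approx(specs[path].mean(),
                                                 rel=0.02)

    def test_drawn_probabilities_stay_in_unit_interval(self, params,
                                                       life_table, annual,
                                                       none_strategy):
        d = run_psa(25, 5, annual, none_strategy, params,
                    life_table).parameter_draws
        for col in d.columns:
            if col.startswith(("utility.", "test_perf.", "disutility_fp")):
                assert ((d[col] >= 0) & (d[col] <= 1)).all()
            if col.startswith("costs."):
                assert (d[col] >= 0).all()


class TestCeac:
    def _draws(self, d_cost, d_qaly, params, life_table, annual,
               none_strategy):
        from bcscreen.sensitivity import PsaDraws
        return PsaDraws(incremental_cost=np.asarray(d_cost, dtype=float),
                        incremental_qaly=np.asarray(d_qaly, dtype=float),
                        seed=0, distribution_specs={}, parameter_draws=None,
                        strategy="annual", comparator="none")

    def test_zero_wtp_with_positive_costs_gives_zero(self, params,
                                                     life_table, annual,
                                                     none_strategy):
        draws = self._draws([10, 20, 30], [0.1, 0.2, 0.3], params,
                            life_table, annual, none_strategy)
        curve = ceac(draws, [0.0])
        assert curve["probability_cost_effective"].iloc[0] == 0.0

    def test_large_wtp_with_positive_effects_approaches_one(self, params,
                                                            life_table,
                                                            annual,
                                                            none_strategy):
        draws = self._draws([10, 20, 30], [0.1, 0.2, 0.3], params,
                            life_table, annual, none_strategy)
        curve = ceac(draws, [1e9])
        assert curve["probability_cost_effective"].iloc[0] == 1.0

    def test_empty_grid_rejected(self, params, life_table, annual,
                                 none_strategy):
        draws = self._draws([1.0], [0.1], params, life_table, annual,
                            none_strategy)
        with pytest.raises(DomainError):
            ceac(draws, [])


class TestScenarios:
    def test_grid_shape_and_warning_without_mammography_alone(
            self, params, life_table):
        with pytest.warns(UserWarning, match="mammography-alone"):
            df = run_scenarios(params, life_table)
        assert list(df["strategy"]) == ["none", "annual", "q3", "q5",
                                        "annual_70pct_uptake"]

    def test_mammography_alone_rows_when_configured(self, params,
                                                    life_table):
        from bcscreen import load_parameters
        p = load_parameters({"test_perf": {"mammography_alone": {
            "sensitivity": {"baseline": 0.85},
            "specificity": {"baseline": 0.96}}}})
        df = run_scenarios(p, life_table)
        assert (df["scenario"] == "mammography alone").sum() == 3

    def test_full_uptake_scenario_equals_baseline_annual(self, params,
                                                         life_table):
        from bcscreen import Strategy, run_cohort, strategy_by_name
        full = Strategy(name="x", screening_interval_years=1,
                        treatment_uptake=1.0)
        a = run_cohort(full, params, life_table)
        b = run_cohort(strategy_by_name("annual"), params, life_table)
        assert a.discounted_cost == pytest.approx(b.discounted_cost)
        assert a.discounted_qaly == pytest.approx(b.discounted_qaly)

    def test_partial_uptake_raises_icer(self, params, life_table,
                                        baseline_results):
        from bcscreen import compare
        base = compare(baseline_results["annual"], baseline_results["none"],
                       params.wtp_threshold)
        partial = compare(baseline_results["annual70"],
                          baseline_results["none"], params.wtp_threshold)
        assert partial.icer > base.icer
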