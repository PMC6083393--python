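"""Parameter loading, validation, strategies and life tables."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcscreen import (LifeTable, ModelParameters, Strategy, load_parameters,
                      onset_probability, serialize_parameters,
                      strategy_by_name, synthetic_life_table)
from bcscreen.errors import (ConfigurationError, DomainError, ValidationError)
from bcscreen.parameters import _band_for_age, bundled_config_path


class TestLoading:
    def test_defaults_reproduce_programme_baselines(self, params):
        assert params.progression["stage_i_to_ii"] == 0.06
        assert params.progression["stage_ii_to_iii"] == 0.11
        assert params.progression["stage_iii_to_iv"] == 0.15
        assert params.progression["stage_iv_to_death"] == 0.23
        assert params.utility_array().tolist() == [0.79, 0.79, 0.77, 0.69]
        assert params.symptom_array().tolist() == [0.004, 0.014, 0.380, 0.980]
        assert params.fatality_array().tolist() == [0.006, 0.042, 0.093, 0.275]
        assert params.costs["screening"].baseline == 85.5
        assert params.discount_rate == 0.03
        assert params.wtp_threshold == 23050.0

    def test_bundled_config_equals_defaults(self, params):
        assert load_parameters(bundled_config_path()).to_dict() == \
            params.to_dict()

    def test_partial_override_keeps_other_defaults(self, params):
        p = load_parameters({"discount_rate": 0.05})
        assert p.discount_rate == 0.05
        assert p.progression == params.progression

    def test_round_trip_serialization(self, params):
        text = serialize_parameters(params)
        assert load_parameters(io.StringIO(text)).to_dict() == params.to_dict()

    @pytest.mark.parametrize("override, message", [
        ({"utility": {"stage_i": {"baseline": 1.3}}}, "utility.stage_i"),
        ({"progression": {"stage_i_to_ii": -0.1}}, "progression.stage_i_to_ii"),
        ({"costs": {"biopsy": {"baseline": -5.0}}}, "costs.biopsy"),
        ({"disutility_fp": {"baseline": 0.5, "min": 0.6, "max": 0.7}},
         "disutility_fp"),
    ])
    def test_out_of_range_values_name_the_field(self, override, message):
        with pytest.raises(ValidationError, match=message.replace(".", r"\.")):
            load_parameters(override)

    def test_explicitly_nulled_section_is_a_missing_key(self):
        with pytest.raises(ConfigurationError, match="progression"):
            load_parameters({"progression": None})

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            load_parameters({"treatment_cost": 1.0})

    def test_with_value_updates_nested_baseline(self, params):
        p = params.with_value("costs.treatment.stage_i", 9000.0)
        assert p.costs["treatment"]["stage_i"].baseline == 9000.0
        # untouched siblings keep their ranges
        assert p.costs["treatment"]["stage_ii"].has_range


class TestOnsetProbability:
    def test_high_risk_scaling_of_band_incidence(self, params):
        assert onset_probability(47, params, "invasive") == \
            pytest.approx(2 * 0.0010056)

    def test_dcis_onset_is_ratio_of_invasive(self, params):
        assert onset_probability(47, params, "dcis") == \
            pytest.approx(0.12 * 2 * 0.0010056)

    def test_identity_at_unit_relative_risk(self, params):
        assert onset_probability(47, params, "invasive", rr_override=1.0) == \
            pytest.approx(0.0010056)

    def test_age_below_entry_is_domain_error(self, params):
        with pytest.raises(DomainError):
            onset_probability(39, params)

    @given(age=st.integers(min_value=40, max_value=100),
           rr=st.floats(min_value=0.1, max_value=20.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_scales_linearly_in_relative_risk_and_stays_a_probability(
            self, age, rr):
        params = load_parameters({})
        base = onset_probability(age, params, "invasive", rr_override=1.0)
        scaled = onset_probability(age, params, "invasive", rr_override=rr)
        assert scaled == pytest.approx(min(rr * base, 1.0))
        assert 0.0 <= scaled <= 1.0

    @pytest.mark.parametrize("age, band", [
        (40, "40-44"), (44, "40-44"), (45, "45-49"), (84, "80-84"),
        (85, "85+"), (100, "85+"),
    ])
    def test_age_band_lookup_uses_closed_inclusive_bands(self, age, band):
        assert _band_for_age(age) == band


class TestStrategy:
    def test_named_strategies(self):
        assert strategy_by_name("none").screening_interval_years == 0
        assert strategy_by_name("annual").screening_ages() == \
            tuple(range(40, 70))
        assert strategy_by_name("q3").screening_ages() == \
            tuple(range(40, 70, 3))
        assert strategy_by_name("q5").screening_ages() == \
            tuple(range(40, 70, 5))

    def test_modality_by_age_band(self):
        s = strategy_by_name("annual")
        assert s.modality_for_age(42) == "ultrasound_then_mammography"
        assert s.modality_for_age(45) == "ultrasound_plus_mammography"
        assert s.modality_for_age(72) is None

    def test_bands_must_tile_eligible_range(self):
        with pytest.raises(ValidationError, match="tile"):
            Strategy(name="bad", screening_interval_years=1,
                     modality_by_age_band=(((40, 44), "x"),
                                           ((50, 69), "y")))

    def test_uptake_bounds(self):
        with pytest.raises(ValidationError):
            Strategy(name="bad", screening_interval_years=1,
                     treatment_uptake=1.2)


class TestLifeTable:
    def test_gompertz_monotone_when_slope_positive(self):
        lt = synthetic_life_table(level=1e-3, slope=0.1)
        q = np.asarray(lt.q)
        assert np.all(np.diff(q) > 0)
        assert np.all((q > 0) & (q < 1))

    def test_zero_slope_gives_constant_mortality(self):
        lt = synthetic_life_table(level=0.01, slope=0.0)
        assert len(set(lt.q)) == 1

    def test_invalid_level_rejected(self):
        with pytest.raises(ValidationError):
            synthetic_life_table(level=0.0)

    def test_discounted_life_expectancy_matches_survival_product(self):
        lt = synthetic_life_table()
        v = 1 / 1.03
        surv, total = 1.0, 0.0
        for t, q in enumerate(lt.q):
            total += surv * v ** t
            surv *= 1 - q
        assert lt.discounted_life_expectancy(0.03) == pytest.approx(
            total, abs=1e-12)

    def test_gapped_table_rejected(self):
        with pytest.raises(ValidationError, match="gaps"):
            LifeTable.from_mapping({40: 0.001, 42: 0.002})

    def test_csv_round_trip(self, tmp_path):
        lt = synthetic_life_table()
        path = tmp_path / "lt.csv"
        lt.to_frame().to_csv(path, index=False)
        again = LifeTable.from_csv(path)
        assert again.start_age == lt.start_age
        assert np.allclose(again.q, lt.q)

    def test_out_of_coverage_age_is_domain_error(self):
        lt = synthetic_life_table()
        with pytest.raises(DomainError):
            lt.q_at(101)
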