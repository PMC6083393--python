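import numpy as np
import pytest

from bcscreen import (Strategy, default_parameters, no_screening, run_cohort,
                      strategy_by_name, synthetic_life_table)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return synthetic_life_table()


@pytest.fixture(scope="session")
def annual():
    return strategy_by_name("annual")


@pytest.fixture(scope="session")
def none_strategy():
    return no_screening()


@pytest.fixture(scope="session")
def baseline_results(params, life_table):
    """Cohort results for the scenario grid, computed once per session."""
    strategies = {
        "none": no_screening(),
        "annual": strategy_by_name("annual"),
        "q3": strategy_by_name("q3"),
        "q5": strategy_by_name("q5"),
        "annual70": Strategy(name="annual70", screening_interval_years=1,
                             treatment_uptake=0.7),
    }
    return {name: run_cohort(s, params, life_table)
            for name, s in strategies.items()}


@pytest.fixture()
def disease_free_params(params):
    """Parameters with cancer onset switched off entirely."""
    d = params.to_dict()
    d["incidence_by_age"] = {b: 0.0 for b in d["incidence_by_age"]}
    d["dcis_ratio"] = 0.0
    from bcscreen import ModelParameters
    return ModelParameters.from_dict(d)
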