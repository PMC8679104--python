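import numpy as np
import pytest

from hhcost import (
    CostParameters,
    CountrySetting,
    EconomicFactors,
    QuantityTable,
    ScenarioSpec,
    ServiceBreakdown,
    build_inputs,
)
from hhcost.synthetic import SyntheticConfig, generate_all, reference_fixture


def make_stratum(
    code="AAA",
    setting="rural",
    household_size=5.0,
    pop0=1_000_000.0,
    growth=0.0,
    no_facility=0.5,
    limited=0.3,
    split=(0.47, 0.10, 0.43),
    piped_share=0.0,
    piped_cost=0.5,
    nonpiped_cost=2.0,
    base_year=2021,
    horizon=10,
):
    basic = 1.0 - no_facility - limited
    return CountrySetting(
        country_code=code,
        setting=setting,
        household_size=household_size,
        population={
            y: pop0 * (1 + growth) ** (y - base_year)
            for y in range(base_year, base_year + horizon)
        },
        service=ServiceBreakdown(no_facility, limited, basic, *split),
        piped_share=piped_share,
        piped_unit_cost=piped_cost,
        nonpiped_unit_cost=nonpiped_cost,
    )


def flat_factors(code="AAA", ppp=2.0, fx=4.0, inflation=0.0):
    years = range(2000, 2031)
    return EconomicFactors(
        country_code=code,
        deflator={y: 100.0 * (1 + inflation) ** (y - 2019) for y in years},
        ppp_lcu_per_int_dollar=ppp,
        fx_lcu_per_usd={y: fx for y in years},
    )


@pytest.fixture
def simple_stratum():
    return make_stratum()


@pytest.fixture
def two_stratum_table():
    urban = make_stratum(setting="urban", pop0=400_000.0, household_size=4.5,
                         no_facility=0.2, limited=0.3, piped_share=0.6)
    rural = make_stratum(setting="rural", pop0=600_000.0, household_size=5.5,
                         no_facility=0.4, limited=0.35)
    return QuantityTable(records=(urban, rural))


@pytest.fixture(scope="session")
def reference_inputs():
    """Reference-46 fixture run through pooling: the canonical model bundle."""
    table, points, factors = reference_fixture()
    return build_inputs(table, list(points), factors)


@pytest.fixture(scope="session")
def small_inputs():
    """A 6-country bundle for fast scenario / Monte Carlo tests."""
    table, points, factors = generate_all(SyntheticConfig(n_countries=6, seed=7))
    return build_inputs(table, points, factors)


@pytest.fixture
def params():
    return CostParameters()


@pytest.fixture
def scenario():
    return ScenarioSpec()
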