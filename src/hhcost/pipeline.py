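"""End-to-end convenience layer tying the stages together.

Raw inputs (country table, price datapoints, economic factors) go through
price standardisation and pooling, deterministic costing, aggregation,
Monte Carlo and the scenario catalogue.  The numbered analysis drivers and
the command-line interface are thin wrappers over these functions.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .costs import PreparedModel, aggregate_total, model_cost_streams
from .params import CostParameters, ScenarioSpec
from .prices import (
    EconomicFactors,
    PricePoint,
    annual_water_price,
    build_price_distributions,
)
from .quantities import QuantityTable
from .sensitivity import ModelInputs
from .uncertainty import McConfig, McResult, run_monte_carlo


def build_inputs(
    table: QuantityTable,
    points: Iterable[PricePoint],
    factors: Mapping[str, EconomicFactors],
    params: CostParameters | None = None,
    scenario: ScenarioSpec | None = None,
) -> ModelInputs:
    """Pool the price datapoints and bundle everything for a model run."""
    return ModelInputs(
        table=table,
        dists=build_price_distributions(points, factors),
        factors=factors,
        params=params or CostParameters(),
        scenario=scenario or ScenarioSpec(),
    )


def population_by_year(table: QuantityTable) -> dict[int, float]:
    """Total population per calendar year across all strata."""
    years = range(table.base_year, table.base_year + table.horizon)
    return {y: float(sum(r.population[y] for r in table)) for y in years}


def per_household_medians(inputs: ModelInputs) -> dict[str, float]:
    """Median localised per-household US$ prices (the per-household framing)."""
    ratios = np.array(
        [inputs.factors[c].ppp_over_fx for c in inputs.table.countries]
    )
    promo = inputs.dists[inputs.scenario.promotion_price_category].i_mean
    water = np.median(
        [annual_water_price(r, inputs.params) for r in inputs.table]
    )
    return {
        "promotion": float(np.median(promo * ratios)),
        "hwf": float(np.median(inputs.dists["hwf"].i_mean * ratios)),
        "soap_annual": float(np.median(inputs.dists["soap_annual"].i_mean * ratios)),
        "water_annual": float(water),
    }


def run_deterministic(inputs: ModelInputs):
    """Full deterministic run: (streams, summary)."""
    streams = model_cost_streams(
        inputs.table, inputs.dists, inputs.factors, inputs.params, inputs.scenario
    )
    summary = aggregate_total(
        streams,
        inputs.params,
        population_by_year=population_by_year(inputs.table),
        per_household_prices=per_household_medians(inputs),
    )
    return streams, summary


def run_probabilistic(inputs: ModelInputs, config: McConfig) -> McResult:
    """Monte Carlo over the prepared model."""
    model = PreparedModel(
        inputs.table, inputs.dists, inputs.factors, inputs.params, inputs.scenario
    )
    return run_monte_carlo(model, config)
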