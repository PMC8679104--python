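"""Deterministic one-way sensitivity analysis (tornado) and scale economies.

Each scenario perturbs a single parameter — a price to its 95 % gamma CI
bound, the discount rate, a useful life, the top-up fraction, the facility
type, the promotion mode, or the economies-of-scale switch — and re-runs
the full deterministic model.  Results are sorted by the absolute swing
between the low and high totals, the ordering a tornado plot displays.
The scenario catalogue ships as data (``data/scenarios.yaml``) so users can
extend it without touching code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .costs import PreparedModel, scale_economy_multipliers
from .params import CostParameters, ScenarioSpec
from .prices import EconomicFactors, PriceDistribution, gamma_from_moments
from .quantities import QuantityTable

_COST_TO_PRICE = {"hwf": "hwf", "soap": "soap_annual", "formative": "formative_research"}


@dataclass(frozen=True)
class ModelInputs:
    """Bundle of everything a deterministic model run needs."""

    table: QuantityTable
    dists: Mapping[str, PriceDistribution]
    factors: Mapping[str, EconomicFactors]
    params: CostParameters
    scenario: ScenarioSpec


@dataclass(frozen=True)
class ScenarioResult:
    """Total-cost endpoints for one perturbation (US$ 2019, discounted)."""

    scenario_id: str
    parameter: str
    base_total: float
    low_total: float
    high_total: float | None = None

    @property
    def swing(self) -> float:
        if self.high_total is None:
            return abs(self.low_total - self.base_total)
        return abs(self.high_total - self.low_total)


def apply_scale_economies(price: float, implementation_year: int) -> float:
    """Unit price after the declining-price schedule, for a given year.

    Reductions on the year-1 price: none in year 1, 10 % in year 2, then
    2-point decrements (8 %, 6 %, 4 %, 2 %) to a total of 30 % from year 6
    onward.  Applies to promotion (and top-up), facilities and soap.
    """
    if implementation_year < 1:
        raise ValueError(f"implementation_year must be >= 1, got {implementation_year}")
    mults = scale_economy_multipliers(max(implementation_year, 1))
    return price * float(mults[implementation_year - 1])


def load_scenario_catalogue(path=None) -> list[dict]:
    """Read scenario definitions from YAML (packaged catalogue by default)."""
    if path is None:
        text = resources.files("hhcost").joinpath("data/scenarios.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    return list(doc["scenarios"])


def _with_mean(dist: PriceDistribution, new_mean: float) -> PriceDistribution:
    shape, scale = gamma_from_moments(new_mean, dist.i_se)
    return dataclasses.replace(
        dist, i_mean=new_mean, gamma_shape=shape, gamma_scale=scale
    )


def _price_category(inputs: ModelInputs, cost_category: str) -> str:
    if cost_category == "promotion":
        return inputs.scenario.promotion_price_category
    try:
        return _COST_TO_PRICE[cost_category]
    except KeyError:
        raise ValueError(f"unknown price category {cost_category!r}") from None


def deterministic_total(inputs: ModelInputs, **replacements) -> float:
    """Discounted 10-year total for the inputs, with optional replacements.

    ``replacements`` may supply ``dists``, ``params``, ``scenario`` or
    ``price_overrides`` (``{cost_category: {country: usd}}``).
    """
    overrides = replacements.pop("price_overrides", None)
    bundle = dataclasses.replace(inputs, **replacements) if replacements else inputs
    if overrides:
        from .costs import aggregate_total, model_cost_streams

        streams = model_cost_streams(
            bundle.table, bundle.dists, bundle.factors, bundle.params, bundle.scenario,
            price_overrides=overrides,
        )
        return aggregate_total(streams, bundle.params)["total_usd2019"]
    model = PreparedModel(
        bundle.table, bundle.dists, bundle.factors, bundle.params, bundle.scenario
    )
    return model.evaluate()["total"]


def _run_one(inputs: ModelInputs, spec: dict, base_total: float) -> ScenarioResult:
    kind = spec.get("kind")
    sid = spec.get("id", kind)
    parameter = spec.get("parameter", sid)

    if kind == "price_ci":
        cost_cat = spec["category"]
        price_cat = _price_category(inputs, cost_cat)
        dist = inputs.dists[price_cat]
        lo_q, hi_q = spec.get("quantiles", (0.025, 0.975))
        totals = []
        for q in (lo_q, hi_q):
            dists = dict(inputs.dists)
            dists[price_cat] = _with_mean(dist, dist.ppf(q))
            totals.append(deterministic_total(inputs, dists=dists))
        lo, hi = sorted(totals)
        return ScenarioResult(sid, parameter, base_total, lo, hi)

    if kind == "price_scale":
        totals = []
        for factor in (spec["low"], spec["high"]):
            dists = {
                cat: _with_mean(d, d.i_mean * factor) for cat, d in inputs.dists.items()
            }
            totals.append(deterministic_total(inputs, dists=dists))
        lo, hi = sorted(totals)
        return ScenarioResult(sid, parameter, base_total, lo, hi)

    if kind == "param_pair":
        field_name = spec["parameter"]
        if field_name not in {f.name for f in dataclasses.fields(CostParameters)}:
            raise ValueError(f"unknown model parameter {field_name!r}")
        totals = []
        for value in (spec["low"], spec["high"]):
            params = dataclasses.replace(inputs.params, **{field_name: value})
            totals.append(deterministic_total(inputs, params=params))
        lo, hi = sorted(totals)
        return ScenarioResult(sid, parameter, base_total, lo, hi)

    if kind == "price_usd_override":
        cost_cat = spec["category"]
        usd = float(spec["usd"])
        overrides = {cost_cat: {code: usd for code in inputs.table.countries}}
        total = deterministic_total(inputs, price_overrides=overrides)
        return ScenarioResult(sid, parameter, base_total, low_total=total)

    if kind == "flag":
        flag = spec["flag"]
        if flag == "economies_of_scale":
            scenario = dataclasses.replace(inputs.scenario, economies_of_scale=True)
        elif flag == "promotion_mode_alternative":
            scenario = dataclasses.replace(inputs.scenario, promotion_mode="alternative")
        elif flag == "promotion_target_whole_population":
            scenario = dataclasses.replace(
                inputs.scenario, promotion_target="whole_population"
            )
        else:
            raise ValueError(f"unknown scenario flag {flag!r}")
        total = deterministic_total(inputs, scenario=scenario)
        return ScenarioResult(sid, parameter, base_total, low_total=total)

    raise ValueError(f"unknown scenario kind {kind!r}")


def run_scenarios(
    inputs: ModelInputs, scenario_defs: Sequence[dict] | None = None
) -> list[ScenarioResult]:
    """One full deterministic model run per perturbation, tornado-sorted."""
    if scenario_defs is None:
        scenario_defs = load_scenario_catalogue()
    base_total = deterministic_total(inputs)
    results = [_run_one(inputs, spec, base_total) for spec in scenario_defs]
    return sorted(results, key=lambda r: r.swing, reverse=True)


def tornado_frame(results: Sequence[ScenarioResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "scenario_id": r.scenario_id,
                "parameter": r.parameter,
                "low_total": r.low_total,
                "high_total": r.high_total if r.high_total is not None else np.nan,
                "base_total": r.base_total,
            }
            for r in results
        ]
    )
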