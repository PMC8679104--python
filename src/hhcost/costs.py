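"""Cost engine: quantities x prices -> discounted cost streams.

One cohort of targeted households is reached per implementation year.  A
cohort reached in year ``s`` incurs, per household: the promotion campaign
at ``s`` and again every ``promo_life`` years within the horizon; top-up
promotion at ``topup_fraction`` of the campaign price in every later year
that is not a full-campaign year; a handwashing facility at ``s`` and again
every ``hwf_life`` years; and soap and water every year from ``s``.
Formative research is a one-off country-level cost in year 1.  Capital
purchases are booked in full in the year incurred with repeat purchases at
end of useful life (no residual-value credit); an equivalent-annual-cost
utility is provided as an alternative reporting mode.  Costs are discounted
to year 1 with exponent ``t - 1`` (year-1 costs undiscounted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .params import (
    CAPITAL_CATEGORIES,
    CATEGORIES,
    RECURRENT_CATEGORIES,
    CostParameters,
    ScenarioSpec,
)
from .prices import EconomicFactors, PriceDistribution, annual_water_price
from .quantities import CountrySetting, QuantityTable, cohort_increments

#: Categories whose unit price declines under the economies-of-scale schedule.
SCALE_ECONOMY_CATEGORIES = frozenset({"promotion", "topup", "hwf", "soap"})


def service_schedule(horizon: int) -> np.ndarray:
    """Cumulative served fraction per implementation year: [1/h, 2/h, ..., 1]."""
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    return np.arange(1, horizon + 1) / horizon


def discount_factors(rate: float, horizon: int) -> np.ndarray:
    """Start-of-year discount factors 1/(1+r)^(t-1) for t = 1..horizon."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return (1.0 + rate) ** -np.arange(horizon)


def scale_economy_multipliers(horizon: int) -> np.ndarray:
    """Unit-price multipliers under the economies-of-scale scenario.

    Prices fall by 10 % of the year-1 price in year 2, then in 2-point
    decrements (8 % in year 3, 6 % in year 4, ...) until the cumulative
    reduction reaches 30 %, where it stays: multipliers
    1.00, 0.90, 0.82, 0.76, 0.72, 0.70, 0.70, ...
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    reductions = np.concatenate([[0.0], np.maximum(0.10 - 0.02 * np.arange(horizon - 1), 0.0)])
    return 1.0 - np.minimum(np.cumsum(reductions), 0.30)


def cohort_cost_profile(category: str, service_year: int, params: CostParameters) -> np.ndarray:
    """Per-household cost multipliers over the horizon for one cohort.

    ``service_year`` is the 1-based implementation year in which the cohort
    receives the intervention.  Capital items carry multiplier 1 in the
    service year and at each repeat purchase (end of useful life) inside the
    horizon; top-up carries ``topup_fraction`` in every later year that is
    not a full-campaign repeat year; soap and water carry 1 from the service
    year onward.  Formative research is booked at country level, not per
    cohort.
    """
    h = params.horizon
    if not 1 <= service_year <= h:
        raise ValueError(f"service_year must be in 1..{h}, got {service_year}")
    years = np.arange(1, h + 1)
    elapsed = years - service_year
    if category == "promotion":
        return np.where((elapsed >= 0) & (elapsed % params.promo_life == 0), 1.0, 0.0)
    if category == "topup":
        promo = (elapsed >= 0) & (elapsed % params.promo_life == 0)
        return np.where((elapsed > 0) & ~promo, params.topup_fraction, 0.0)
    if category == "hwf":
        return np.where((elapsed >= 0) & (elapsed % params.hwf_life == 0), 1.0, 0.0)
    if category in ("soap", "water"):
        return np.where(elapsed >= 0, 1.0, 0.0)
    if category == "formative":
        raise ValueError("formative research is a country-level one-off, not a cohort cost")
    raise ValueError(f"unknown cost category {category!r}")


def equivalent_annual_cost(amount: float, rate: float, life: int) -> float:
    """Annuitise a capital outlay over its useful life at the discount rate.

    With a zero rate this is straight-line ``amount / life``.
    """
    if life < 1:
        raise ValueError(f"life must be >= 1, got {life}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if rate == 0:
        return amount / life
    annuity = (1.0 - (1.0 + rate) ** -life) / rate
    return amount / annuity


@dataclass(frozen=True)
class CostStream:
    """Costs for one (country, setting, category), by implementation year.

    Amounts are 2019 US$.  ``setting`` is ``urban``/``rural``, or
    ``national`` for the country-level formative research stream.
    """

    country_code: str
    setting: str
    category: str
    cost_by_year: np.ndarray
    discounted_by_year: np.ndarray

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown cost category {self.category!r}")
        cost = np.asarray(self.cost_by_year, dtype=float)
        disc = np.asarray(self.discounted_by_year, dtype=float)
        if cost.shape != disc.shape:
            raise ValueError("cost and discounted vectors must have the same length")
        if np.any(cost < 0) or np.any(disc < 0):
            raise ValueError("cost amounts must be non-negative")
        if np.any(disc > cost * (1 + 1e-12) + 1e-9):
            raise ValueError("discounted costs cannot exceed undiscounted costs")

    @property
    def total(self) -> float:
        return float(self.cost_by_year.sum())

    @property
    def discounted_total(self) -> float:
        return float(self.discounted_by_year.sum())


def discount_stream(stream: CostStream, rate: float) -> CostStream:
    """Re-discount a stream's undiscounted profile at ``rate``."""
    df = discount_factors(rate, len(stream.cost_by_year))
    return CostStream(
        country_code=stream.country_code,
        setting=stream.setting,
        category=stream.category,
        cost_by_year=stream.cost_by_year,
        discounted_by_year=stream.cost_by_year * df,
    )


# ---------------------------------------------------------------------------
# Quantity units: household-events per year, before prices

def stratum_unit_years(
    cs: CountrySetting, params: CostParameters, scenario: ScenarioSpec
) -> dict[str, np.ndarray]:
    """Per-category household-event units by year for one stratum.

    ``units[cat][t]`` is the number of per-household price units of category
    ``cat`` purchased in implementation year ``t+1`` (top-up units already
    carry the top-up fraction), so cost = units x unit price.
    """
    h = params.horizon
    promo_target = "all" if scenario.promotion_target == "whole_population" else "no_facility"
    inc_promo = cohort_increments(cs, params, target=promo_target)
    inc_main = (
        inc_promo
        if promo_target == "no_facility"
        else cohort_increments(cs, params, target="no_facility")
    )

    units = {cat: np.zeros(h) for cat in ("promotion", "topup", "hwf", "soap", "water")}
    for s in range(1, h + 1):
        units["promotion"] += inc_promo[s - 1] * cohort_cost_profile("promotion", s, params)
        units["topup"] += inc_promo[s - 1] * cohort_cost_profile("topup", s, params)
        for cat in ("hwf", "soap", "water"):
            units[cat] += inc_main[s - 1] * cohort_cost_profile(cat, s, params)

    if scenario.include_limited_supplies:
        recurrent = {
            "soap": ("limited_soap_only", "limited_both_missing"),
            "water": ("limited_water_only", "limited_both_missing"),
        }
        for cat, targets in recurrent.items():
            for target in targets:
                inc = cohort_increments(cs, params, target=target)
                for s in range(1, h + 1):
                    units[cat] += inc[s - 1] * cohort_cost_profile(cat, s, params)
    return units


def country_cost_stream(
    cs: CountrySetting,
    prices: Mapping[str, float],
    params: CostParameters,
    scenario: ScenarioSpec,
) -> list[CostStream]:
    """Cost streams for one stratum given per-category US$ 2019 unit prices.

    ``prices`` must cover ``promotion``, ``hwf``, ``soap`` and ``water``
    (top-up uses the promotion price; its fraction is baked into the
    units).  Formative research is handled at country level by
    :func:`model_cost_streams`.
    """
    required = ("promotion", "hwf", "soap", "water")
    missing = [c for c in required if c not in prices]
    if missing:
        raise ValueError(
            f"{cs.country_code}/{cs.setting}: missing unit prices for {missing}"
        )
    units = stratum_unit_years(cs, params, scenario)
    df = discount_factors(params.discount_rate, params.horizon)
    esm = (
        scale_economy_multipliers(params.horizon)
        if scenario.economies_of_scale
        else np.ones(params.horizon)
    )
    streams = []
    for cat, u in units.items():
        price = prices["promotion"] if cat == "topup" else prices[cat]
        mult = esm if cat in SCALE_ECONOMY_CATEGORIES else np.ones(params.horizon)
        cost = u * price * mult
        streams.append(
            CostStream(
                country_code=cs.country_code,
                setting=cs.setting,
                category=cat,
                cost_by_year=cost,
                discounted_by_year=cost * df,
            )
        )
    return streams


def model_cost_streams(
    table: QuantityTable,
    dists: Mapping[str, PriceDistribution],
    factors: Mapping[str, EconomicFactors],
    params: CostParameters,
    scenario: ScenarioSpec,
    price_overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> list[CostStream]:
    """Full deterministic model: streams for every stratum plus formative.

    ``dists`` maps price-datapoint categories to pooled distributions; the
    scenario picks which promotion category applies.  ``price_overrides``
    optionally replaces the localised US$ price for given cost categories,
    as ``{cost_category: {country_code: usd}}`` (used by sensitivity
    scenarios such as the home-made facility).
    """
    price_overrides = price_overrides or {}
    promo_cat = scenario.promotion_price_category
    needed = {"promotion": promo_cat, "hwf": "hwf", "soap": "soap_annual",
              "formative": "formative_research"}
    for cost_cat, price_cat in needed.items():
        if cost_cat not in price_overrides and price_cat not in dists:
            raise ValueError(f"missing price distribution {price_cat!r} for {cost_cat}")

    streams: list[CostStream] = []
    df = discount_factors(params.discount_rate, params.horizon)
    for code in table.countries:
        if code not in factors:
            raise ValueError(f"no economic factors for {code}")
        ratio = factors[code].ppp_over_fx

        def local(cost_cat: str) -> float:
            if cost_cat in price_overrides:
                return price_overrides[cost_cat][code]
            return dists[needed[cost_cat]].i_mean * ratio

        for r in table:
            if r.country_code != code:
                continue
            prices = {
                "promotion": local("promotion"),
                "hwf": local("hwf"),
                "soap": local("soap"),
                "water": annual_water_price(r, params),
            }
            streams.extend(country_cost_stream(r, prices, params, scenario))

        formative_cost = np.zeros(params.horizon)
        formative_cost[0] = local("formative")
        streams.append(
            CostStream(
                country_code=code,
                setting="national",
                category="formative",
                cost_by_year=formative_cost,
                discounted_by_year=formative_cost * df,
            )
        )
    return streams


# ---------------------------------------------------------------------------
# Aggregation

def aggregate_total(
    streams: Sequence[CostStream],
    params: CostParameters,
    population_by_year: Mapping[int, float] | None = None,
    per_household_prices: Mapping[str, float] | None = None,
) -> dict:
    """Summarise streams into the reporting quantities.

    Returns discounted 10-year totals by category and overall, annual
    averages, integer-percent category shares, the capital/recurrent split
    (capital = formative + promotion + facility; top-up is recurrent), the
    promotion-only block (formative + promotion + top-up) and the
    facilities-and-supplies block (facility + soap + water), plus per-head
    figures when a population denominator is supplied and a per-household
    price block when median localised prices are supplied.
    """
    if not streams:
        raise ValueError("no cost streams to aggregate")
    h = params.horizon
    by_cat = {cat: np.zeros(h) for cat in CATEGORIES}
    by_cat_undisc = {cat: np.zeros(h) for cat in CATEGORIES}
    for s in streams:
        by_cat[s.category] += s.discounted_by_year
        by_cat_undisc[s.category] += s.cost_by_year

    totals = {cat: float(v.sum()) for cat, v in by_cat.items()}
    grand = float(sum(totals.values()))
    if grand <= 0:
        raise ValueError("aggregate total is zero; nothing to report")
    capital = sum(totals[c] for c in CAPITAL_CATEGORIES)
    recurrent = sum(totals[c] for c in RECURRENT_CATEGORIES)
    promotion_block = totals["formative"] + totals["promotion"] + totals["topup"]
    supplies_block = totals["hwf"] + totals["soap"] + totals["water"]

    summary = {
        "horizon": h,
        "discount_rate": params.discount_rate,
        "total_usd2019": grand,
        "average_annual_usd2019": grand / h,
        "category_totals_usd2019": totals,
        "category_average_annual_usd2019": {c: t / h for c, t in totals.items()},
        "category_shares": {c: t / grand for c, t in totals.items()},
        "category_shares_pct": {c: int(round(100 * t / grand)) for c, t in totals.items()},
        "capital_total_usd2019": capital,
        "recurrent_total_usd2019": recurrent,
        "capital_share_pct": int(round(100 * capital / grand)),
        "recurrent_share_pct": int(round(100 * recurrent / grand)),
        "promotion_only_total_usd2019": promotion_block,
        "facilities_supplies_total_usd2019": supplies_block,
        "by_year_usd2019": {c: v.tolist() for c, v in by_cat.items()},
        "by_year_undiscounted_usd2019": {c: v.tolist() for c, v in by_cat_undisc.items()},
    }
    if population_by_year:
        mean_pop = float(np.mean(list(population_by_year.values())))
        summary["per_head"] = {
            "mean_population": mean_pop,
            "annual_total_usd2019": grand / h / mean_pop,
            "annual_promotion_usd2019": promotion_block / h / mean_pop,
            "annual_facilities_supplies_usd2019": supplies_block / h / mean_pop,
        }
    if per_household_prices:
        summary["per_household_usd2019"] = dict(per_household_prices)
    return summary


def streams_frame(streams: Sequence[CostStream], params: CostParameters):
    """Long-form table of all streams (one row per country/setting/category/year)."""
    import pandas as pd

    rows = []
    for s in streams:
        for t in range(params.horizon):
            rows.append(
                {
                    "country_code": s.country_code,
                    "setting": s.setting,
                    "category": s.category,
                    "year": params.base_year + t,
                    "cost_usd2019": float(s.cost_by_year[t]),
                    "discounted_usd2019": float(s.discounted_by_year[t]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Prepared (linearised) model for repeated price evaluations

@dataclass
class PreparedModel:
    """Cost model with quantities precomputed, evaluable at arbitrary prices.

    Every category's discounted total is linear in its pooled I$ mean
    (localisation multiplies by a country ratio; costing multiplies by
    quantity units), so the model reduces to one coefficient per cost
    category — the discounted US$ total per I$ of pooled mean — plus the
    fixed water total, which is constructed from tariffs rather than pooled
    datapoints.  Evaluating at the point means reproduces the stream-based
    model exactly; Monte Carlo draws re-evaluate at sampled means.
    """

    table: QuantityTable
    dists: Mapping[str, PriceDistribution]
    factors: Mapping[str, EconomicFactors]
    params: CostParameters
    scenario: ScenarioSpec
    coefficients: dict[str, float] = field(init=False)
    water_total: float = field(init=False)

    def __post_init__(self) -> None:
        h = self.params.horizon
        df = discount_factors(self.params.discount_rate, h)
        esm = (
            scale_economy_multipliers(h)
            if self.scenario.economies_of_scale
            else np.ones(h)
        )
        coeff = {cat: 0.0 for cat in ("promotion", "topup", "hwf", "soap", "formative")}
        water = 0.0
        for r in self.table:
            if r.country_code not in self.factors:
                raise ValueError(f"no economic factors for {r.country_code}")
            ratio = self.factors[r.country_code].ppp_over_fx
            units = stratum_unit_years(r, self.params, self.scenario)
            for cat, u in units.items():
                mult = esm if cat in SCALE_ECONOMY_CATEGORIES else np.ones(h)
                value = float((u * mult * df).sum())
                if cat == "water":
                    water += value * annual_water_price(r, self.params)
                else:
                    coeff[cat] += value * ratio
        for code in self.table.countries:
            coeff["formative"] += self.factors[code].ppp_over_fx * float(df[0])
        self.coefficients = coeff
        self.water_total = water

    def point_means(self) -> dict[str, float]:
        """Pooled I$ means at the scenario's active price categories."""
        return {
            "promotion": self.dists[self.scenario.promotion_price_category].i_mean,
            "hwf": self.dists["hwf"].i_mean,
            "soap": self.dists["soap_annual"].i_mean,
            "formative": self.dists["formative_research"].i_mean,
        }

    def evaluate(
        self, i_means: Mapping[str, float] | None = None, water_scale: float = 1.0
    ) -> dict[str, float]:
        """Discounted category totals (US$ 2019) at the given pooled I$ means.

        ``i_means`` keys are cost categories (``promotion``, ``hwf``,
        ``soap``, ``formative``); top-up always follows the promotion mean.
        """
        m = dict(self.point_means())
        if i_means:
            m.update(i_means)
        totals = {
            "formative": m["formative"] * self.coefficients["formative"],
            "promotion": m["promotion"] * self.coefficients["promotion"],
            "topup": m["promotion"] * self.coefficients["topup"],
            "hwf": m["hwf"] * self.coefficients["hwf"],
            "soap": m["soap"] * self.coefficients["soap"],
            "water": self.water_total * water_scale,
        }
        totals["total"] = float(sum(totals.values()))
        totals["promotion_only"] = totals["formative"] + totals["promotion"] + totals["topup"]
        totals["facilities_supplies"] = totals["hwf"] + totals["soap"] + totals["water"]
        return totals
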