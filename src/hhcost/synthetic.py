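"""Synthetic country tables, price datapoints and economic factors.

The generator emulates the statistical structure of the model's inputs so
every stage of the pipeline is exercisable without downloads: country x
{urban, rural} strata with service breakdowns summing to one and limited
splits centred on 47/10/43 (soap missing / water missing / both),
exponential population growth at country-specific rates, right-skewed gamma
price datapoints carrying heterogeneous currencies and price years, and
smooth deflator/PPP/exchange-rate series with the low price levels (PPP to
exchange-rate ratio below one) typical of least developed economies.

Price datapoints are calibrated so that, after the full standardise → pool
→ localise pipeline, the localised median across countries lands on the
per-category US$ anchors (the drawn sample's median is rescaled exactly
onto the target; the gamma's shape supplies the right skew).  Raw amounts
are back-computed into each datapoint's local currency and price year, so
standardisation is genuinely exercised and inverts the construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from string import ascii_uppercase
from typing import Mapping

import numpy as np
from scipy import stats

from .prices import EconomicFactors, PricePoint, REFERENCE_YEAR
from .quantities import CountrySetting, QuantityTable, ServiceBreakdown

#: Default per-household US$ price anchors (medians after localisation).
DEFAULT_ANCHORS: dict[str, float] = {
    "promotion_base": 33.9,
    "promotion_alternative": 19.4,
    "hwf": 14.8,
    "soap_annual": 14.8,
    "hwf_homemade": 1.2,
}
#: Formative research is anchored on its US$ *mean* per intervention.
FORMATIVE_MEAN_USD = 100_000.0

#: Datapoint counts per category (promotion/facility/soap/formative follow
#: the source-study counts; the alternative-promotion and home-made-facility
#: samples are smaller subsets).
DEFAULT_COUNTS: dict[str, int] = {
    "promotion_base": 14,
    "hwf": 16,
    "soap_annual": 10,
    "formative_research": 5,
    "promotion_alternative": 8,
    "hwf_homemade": 6,
}

REFERENCE_SEED = 46


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic-input generator.

    Defaults emulate the 46 least-developed-country study frame: ~1 billion
    people across countries of log-normal size, predominantly rural
    populations, roughly a third of households with no handwashing
    facility, and price levels (PPP/FX ratio) between 0.24 and 0.43.
    """

    n_countries: int = 46
    seed: int = REFERENCE_SEED
    base_year: int = 2021
    horizon: int = 10
    # population
    pop_median: float = 1.2e7
    pop_sigma: float = 1.1
    urban_share_range: tuple[float, float] = (0.20, 0.45)
    growth_rate_range: tuple[float, float] = (0.015, 0.03)
    household_size_urban: tuple[float, float] = (4.0, 5.5)
    household_size_rural: tuple[float, float] = (4.5, 6.5)
    # hygiene service structure (no facility / limited / basic)
    service_mean_urban: tuple[float, float, float] = (0.18, 0.27, 0.55)
    service_mean_rural: tuple[float, float, float] = (0.38, 0.33, 0.29)
    coverage_concentration: float = 25.0
    limited_split_mean: tuple[float, float, float] = (0.47, 0.10, 0.43)
    limited_split_concentration: float = 60.0
    # water supply
    piped_share_urban: tuple[float, float] = (0.30, 0.70)
    piped_share_rural: tuple[float, float] = (0.02, 0.25)
    piped_tariff_range: tuple[float, float] = (0.30, 1.00)
    nonpiped_cost_range: tuple[float, float] = (1.00, 4.00)
    # prices
    price_anchor_medians: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS)
    )
    price_counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    price_cv: float = 0.5
    usd_reporting_share: float = 0.3
    price_year_range: tuple[int, int] = (2012, 2019)
    # economic factors
    inflation_range: tuple[float, float] = (0.02, 0.10)
    ppp_fx_ratio_range: tuple[float, float] = (0.24, 0.43)
    fx_median: float = 100.0
    fx_sigma: float = 1.5
    deflator_years: tuple[int, int] = (2010, 2030)

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        for name in (
            "urban_share_range",
            "growth_rate_range",
            "household_size_urban",
            "household_size_rural",
            "piped_share_urban",
            "piped_share_rural",
            "piped_tariff_range",
            "nonpiped_cost_range",
            "inflation_range",
            "ppp_fx_ratio_range",
            "price_year_range",
            "deflator_years",
        ):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be an ordered interval, got ({lo}, {hi})")
        if self.price_cv <= 0:
            raise ValueError("price_cv must be positive")
        if any(v <= 0 for v in self.price_anchor_medians.values()):
            raise ValueError("price anchors must be positive")

    def country_codes(self) -> list[str]:
        codes = ("".join(t) for t in product(ascii_uppercase, repeat=3))
        return [next(codes) for _ in range(self.n_countries)]


def _uniform(rng: np.random.Generator, interval: tuple[float, float]) -> float:
    return float(rng.uniform(*interval))


# ---------------------------------------------------------------------------
# Country table

def generate_country_table(config: SyntheticConfig) -> QuantityTable:
    """Deterministic synthetic country x setting table."""
    rng = np.random.default_rng(config.seed)
    records = []
    years = range(config.base_year, config.base_year + config.horizon)
    for code in config.country_codes():
        pop_total = float(rng.lognormal(np.log(config.pop_median), config.pop_sigma))
        urban_share = _uniform(rng, config.urban_share_range)
        growth = _uniform(rng, config.growth_rate_range)
        for setting, share, hh_range, service_mean, piped_range in (
            ("urban", urban_share, config.household_size_urban,
             config.service_mean_urban, config.piped_share_urban),
            ("rural", 1.0 - urban_share, config.household_size_rural,
             config.service_mean_rural, config.piped_share_rural),
        ):
            base_pop = pop_total * share
            population = {
                y: base_pop * (1.0 + growth) ** (y - config.base_year) for y in years
            }
            service_shares = rng.dirichlet(
                np.asarray(service_mean) * config.coverage_concentration
            )
            limited_split = rng.dirichlet(
                np.asarray(config.limited_split_mean) * config.limited_split_concentration
            )
            records.append(
                CountrySetting(
                    country_code=code,
                    setting=setting,
                    household_size=_uniform(rng, hh_range),
                    population=population,
                    service=ServiceBreakdown(
                        no_facility=float(service_shares[0]),
                        limited=float(service_shares[1]),
                        basic=float(service_shares[2]),
                        limited_soap_only=float(limited_split[0]),
                        limited_water_only=float(limited_split[1]),
                        limited_both_missing=float(limited_split[2]),
                    ),
                    piped_share=_uniform(rng, piped_range),
                    piped_unit_cost=_uniform(rng, config.piped_tariff_range),
                    nonpiped_unit_cost=_uniform(rng, config.nonpiped_cost_range),
                    data_provenance="observed",
                )
            )
    return QuantityTable(
        records=tuple(records), base_year=config.base_year, horizon=config.horizon
    )


def ldc_average_breakdown(table: QuantityTable) -> ServiceBreakdown:
    """Population-weighted average service breakdown across a table."""
    year = table.base_year
    w = np.array([r.population[year] for r in table])
    cols = np.array(
        [
            [
                r.service.no_facility,
                r.service.limited,
                r.service.basic,
                r.service.limited_soap_only,
                r.service.limited_water_only,
                r.service.limited_both_missing,
            ]
            for r in table
            if r.service is not None
        ]
    )
    avg = (cols * w[:, None]).sum(axis=0) / w.sum()
    avg[:3] /= avg[:3].sum()
    avg[3:] /= avg[3:].sum()
    return ServiceBreakdown(*avg)


# ---------------------------------------------------------------------------
# Economic factors

def generate_economic_factors(config: SyntheticConfig) -> dict[str, EconomicFactors]:
    """Deterministic deflator / PPP / exchange-rate series per country."""
    rng = np.random.default_rng(config.seed + 1)
    y0, y1 = config.deflator_years
    out: dict[str, EconomicFactors] = {}
    for code in config.country_codes():
        inflation = _uniform(rng, config.inflation_range)
        deflator = {
            y: 100.0 * (1.0 + inflation) ** (y - REFERENCE_YEAR) for y in range(y0, y1 + 1)
        }
        fx_2019 = float(rng.lognormal(np.log(config.fx_median), config.fx_sigma))
        # nominal depreciation loosely tracks inflation
        fx = {y: fx_2019 * (deflator[y] / 100.0) ** 0.8 for y in range(y0, y1 + 1)}
        fx[REFERENCE_YEAR] = fx_2019
        ratio = _uniform(rng, config.ppp_fx_ratio_range)
        out[code] = EconomicFactors(
            country_code=code,
            deflator=deflator,
            ppp_lcu_per_int_dollar=fx_2019 * ratio,
            fx_lcu_per_usd=fx,
        )
    return out


# ---------------------------------------------------------------------------
# Price datapoints

def _gamma_scale_for_median(target_median: float, shape: float) -> float:
    return target_median / float(stats.gamma.ppf(0.5, a=shape))


def generate_price_points(
    config: SyntheticConfig, factors: Mapping[str, EconomicFactors]
) -> list[PricePoint]:
    """Right-skewed datapoints whose localised medians hit the US$ anchors.

    Each point is assigned a study country and price year and back-converted
    into the raw amount (local currency, or US$ for a share of points) that
    standardisation will turn back into the intended I$ value.
    """
    rng = np.random.default_rng(config.seed + 2)
    codes = sorted(factors)
    ratios = np.array([factors[c].ppp_over_fx for c in codes])
    median_ratio = float(np.median(ratios))
    mean_ratio = float(np.mean(ratios))
    shape = 1.0 / config.price_cv**2

    points: list[PricePoint] = []
    for category, n in config.price_counts.items():
        if category == "formative_research":
            target_mean_i = FORMATIVE_MEAN_USD / mean_ratio
            draws = rng.gamma(shape=shape, scale=target_mean_i / shape, size=n)
            draws *= target_mean_i / draws.mean()
        else:
            anchor = config.price_anchor_medians[category]
            target_median_i = anchor / median_ratio
            scale = _gamma_scale_for_median(target_median_i, shape)
            draws = rng.gamma(shape=shape, scale=scale, size=n)
            draws *= target_median_i / np.median(draws)
        for j, i_dollar in enumerate(draws):
            code = codes[int(rng.integers(len(codes)))]
            ef = factors[code]
            y0, y1 = config.price_year_range
            price_year = int(rng.integers(y0, y1 + 1))
            amount_lcu_2019 = i_dollar * ef.ppp_lcu_per_int_dollar
            amount_py = (
                amount_lcu_2019 * ef.deflator[price_year] / ef.deflator[REFERENCE_YEAR]
            )
            in_usd = rng.random() < config.usd_reporting_share
            points.append(
                PricePoint(
                    category=category,
                    amount=float(
                        amount_py / ef.fx_lcu_per_usd[price_year] if in_usd else amount_py
                    ),
                    currency="USD" if in_usd else code,
                    price_year=price_year,
                    country_code=code,
                    scope="per_household",
                    source_id=f"{category}-{j:02d}",
                )
            )
    return points


# ---------------------------------------------------------------------------
# Bundles

def generate_all(
    config: SyntheticConfig,
) -> tuple[QuantityTable, list[PricePoint], dict[str, EconomicFactors]]:
    """Country table, price datapoints and economic factors for one config."""
    table = generate_country_table(config)
    factors = generate_economic_factors(config)
    points = generate_price_points(config, factors)
    return table, points, factors


@lru_cache(maxsize=1)
def reference_fixture() -> tuple[QuantityTable, tuple[PricePoint, ...], Mapping[str, EconomicFactors]]:
    """The canonical frozen fixture: 46 countries, seed 46 ("reference-46")."""
    table, points, factors = generate_all(SyntheticConfig())
    return table, tuple(points), factors
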