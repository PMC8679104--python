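"""Price standardisation, pooling and re-localisation.

Raw price datapoints from field studies arrive in heterogeneous currencies
and years.  Each is first expressed in the study country's local currency,
inflated to 2019 with the country's GDP deflator, and converted to 2019
international dollars (I$) with the PPP conversion factor.  Pooling happens
in I$ because a US$ mean would be biased by purchasing power: the same I$
amount buys the same basket everywhere, but converts to very different US$
amounts in low- and high-price countries.  Pooled I$ means carry a standard
error and are modelled as gamma distributed (price data are right-skewed);
the pooled mean is then re-localised to 2019 US$ per country via the
country's PPP/exchange-rate ratio.

The annual household water price is constructed, not pooled: handwashing
water volume (litres/person/day x household size) priced at the blend of
piped tariff and non-piped unit cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import PRICE_CATEGORIES, CostParameters
from .quantities import CountrySetting

REFERENCE_YEAR = 2019


@dataclass(frozen=True)
class PricePoint:
    """One raw price datapoint from a source study."""

    category: str
    amount: float
    currency: str  # "USD" or the study country's local currency code
    price_year: int
    country_code: str
    scope: str = "per_household"
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.category not in PRICE_CATEGORIES:
            raise ValueError(f"unknown price category {self.category!r}")
        if not self.amount > 0:
            raise ValueError(f"amount must be > 0, got {self.amount}")
        if not 1990 <= self.price_year <= 2030:
            raise ValueError(f"price_year must be in [1990, 2030], got {self.price_year}")
        if self.scope not in ("per_household", "per_intervention"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class EconomicFactors:
    """World-Bank-style deflator, PPP and exchange-rate series for one country.

    ``deflator`` is a GDP deflator index with base 2019 = 100;
    ``ppp_lcu_per_int_dollar`` is the 2019 PPP conversion factor (local
    currency units per I$); ``fx_lcu_per_usd`` maps years to market exchange
    rates (LCU per US$), and must cover 2019.
    """

    country_code: str
    deflator: Mapping[int, float]
    ppp_lcu_per_int_dollar: float
    fx_lcu_per_usd: Mapping[int, float]

    def __post_init__(self) -> None:
        if REFERENCE_YEAR not in self.deflator:
            raise ValueError(f"{self.country_code}: deflator must be defined for 2019")
        if any(v <= 0 for v in self.deflator.values()):
            raise ValueError(f"{self.country_code}: deflator values must be positive")
        if not self.ppp_lcu_per_int_dollar > 0:
            raise ValueError(f"{self.country_code}: PPP factor must be positive")
        if REFERENCE_YEAR not in self.fx_lcu_per_usd:
            raise ValueError(f"{self.country_code}: exchange rate must cover 2019")
        if any(v <= 0 for v in self.fx_lcu_per_usd.values()):
            raise ValueError(f"{self.country_code}: exchange rates must be positive")

    @property
    def fx_2019(self) -> float:
        return self.fx_lcu_per_usd[REFERENCE_YEAR]

    @property
    def ppp_over_fx(self) -> float:
        """Price-level ratio: US$ value of one I$ in this country."""
        return self.ppp_lcu_per_int_dollar / self.fx_2019


@dataclass(frozen=True)
class PriceDistribution:
    """Pooled per-category price: I$ mean, SE and the matched gamma prior."""

    category: str
    i_mean: float
    i_se: float
    gamma_shape: float
    gamma_scale: float
    n_points: int
    se_is_fallback: bool = False

    def __post_init__(self) -> None:
        if abs(self.gamma_shape * self.gamma_scale - self.i_mean) > 1e-9 * max(1.0, self.i_mean):
            raise ValueError("gamma parameters inconsistent with i_mean")
        if abs(self.gamma_shape * self.gamma_scale**2 - self.i_se**2) > 1e-9 * max(
            1.0, self.i_se**2
        ):
            raise ValueError("gamma parameters inconsistent with i_se")

    def ppf(self, q: float) -> float:
        """Quantile of the gamma prior (used for CI-bound scenarios)."""
        return float(stats.gamma.ppf(q, a=self.gamma_shape, scale=self.gamma_scale))


@dataclass(frozen=True)
class LocalPrice:
    """Pooled price re-localised to one country, 2019 US$."""

    country_code: str
    category: str
    usd_2019: float

    def __post_init__(self) -> None:
        if not self.usd_2019 > 0:
            raise ValueError(f"usd_2019 must be > 0, got {self.usd_2019}")


# ---------------------------------------------------------------------------
# Standardisation

def standardize_price(pp: PricePoint, ef: EconomicFactors) -> float:
    """Express a raw datapoint in 2019 international dollars.

    Amounts reported in US$ are first converted to the study country's
    local currency at the price-year exchange rate — inflation must be
    applied in the economy where the price arose — then inflated with the
    GDP deflator and divided by the PPP factor.
    """
    if ef.country_code != pp.country_code:
        raise ValueError(
            f"factors are for {ef.country_code}, datapoint is from {pp.country_code}"
        )
    if pp.price_year not in ef.deflator:
        raise ValueError(
            f"{ef.country_code}: deflator missing for year {pp.price_year}"
        )
    if pp.currency == "USD":
        if pp.price_year not in ef.fx_lcu_per_usd:
            raise ValueError(
                f"{ef.country_code}: exchange rate missing for year {pp.price_year}"
            )
        amount_lcu = pp.amount * ef.fx_lcu_per_usd[pp.price_year]
    else:
        amount_lcu = pp.amount
    amount_lcu_2019 = amount_lcu * ef.deflator[REFERENCE_YEAR] / ef.deflator[pp.price_year]
    return amount_lcu_2019 / ef.ppp_lcu_per_int_dollar


# ---------------------------------------------------------------------------
# Pooling

def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Moment-match a gamma distribution: shape = (mean/se)^2, scale = se^2/mean."""
    if not mean > 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if not se > 0:
        raise ValueError(f"se must be > 0, got {se}")
    return (mean / se) ** 2, se**2 / mean


def pool_prices(
    points: Sequence[float],
    category: str,
    fallback_cv: float | None = 0.25,
) -> PriceDistribution:
    """Pool standardised I$ amounts into a per-category distribution.

    The SE of the pooled mean is sample SD / sqrt(n).  With a single
    datapoint the SE is imputed as ``mean x fallback_cv`` and flagged; with
    identical points the SE degenerates to zero and no gamma prior exists —
    supply a minimum-SE floor by re-pooling with a perturbed value or use a
    fallback CV explicitly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size < 1:
        raise ValueError("at least one price point is required")
    if np.any(pts <= 0):
        raise ValueError("price points must be strictly positive")
    mean = float(pts.mean())
    fallback = False
    if pts.size == 1:
        if fallback_cv is None or fallback_cv <= 0:
            raise ValueError(
                f"{category}: single datapoint requires a positive fallback_cv"
            )
        se = mean * fallback_cv
        fallback = True
    else:
        se = float(pts.std(ddof=1) / np.sqrt(pts.size))
        if se == 0.0:
            raise ValueError(
                f"{category}: all datapoints identical, SE is 0 and the gamma prior "
                f"is degenerate; apply a minimum-SE floor (e.g. pool with a fallback CV)"
            )
    shape, scale = gamma_from_moments(mean, se)
    return PriceDistribution(
        category=category,
        i_mean=mean,
        i_se=se,
        gamma_shape=shape,
        gamma_scale=scale,
        n_points=int(pts.size),
        se_is_fallback=fallback,
    )


def median_cv(groups: Mapping[str, Sequence[float]]) -> float:
    """Median coefficient of variation (of the mean) across categories with n >= 2.

    Used as the fallback CV for categories with a single datapoint.
    """
    cvs = []
    for pts in groups.values():
        arr = np.asarray(pts, dtype=float)
        if arr.size >= 2 and arr.mean() > 0:
            cvs.append(arr.std(ddof=1) / np.sqrt(arr.size) / arr.mean())
    if not cvs:
        raise ValueError("no category with >= 2 datapoints; cannot derive a fallback CV")
    return float(np.median(cvs))


def build_price_distributions(
    points: Iterable[PricePoint],
    factors: Mapping[str, EconomicFactors],
) -> dict[str, PriceDistribution]:
    """Standardise all datapoints and pool them per category.

    Single-datapoint categories get a fallback SE from the median CV
    observed across the categories with two or more points.
    """
    grouped: dict[str, list[float]] = {}
    for pp in points:
        if pp.country_code not in factors:
            raise ValueError(f"no economic factors for {pp.country_code}")
        grouped.setdefault(pp.category, []).append(
            standardize_price(pp, factors[pp.country_code])
        )
    multi = {c: v for c, v in grouped.items() if len(v) >= 2}
    fallback_cv = median_cv(multi) if multi else 0.25
    return {
        cat: pool_prices(vals, cat, fallback_cv=fallback_cv)
        for cat, vals in grouped.items()
    }


# ---------------------------------------------------------------------------
# Localisation

def localize_price(dist: PriceDistribution, ef: EconomicFactors) -> LocalPrice:
    """Re-express a pooled I$ mean as 2019 US$ in one country."""
    return LocalPrice(
        country_code=ef.country_code,
        category=dist.category,
        usd_2019=dist.i_mean * ef.ppp_over_fx,
    )


def localize_all(
    dists: Mapping[str, PriceDistribution],
    factors: Mapping[str, EconomicFactors],
) -> dict[tuple[str, str], float]:
    """US$ 2019 price per (country, category)."""
    return {
        (code, cat): localize_price(dist, ef).usd_2019
        for code, ef in factors.items()
        for cat, dist in dists.items()
    }


# ---------------------------------------------------------------------------
# Water

def annual_water_price(cs: CountrySetting, params: CostParameters) -> float:
    """Annual household cost of handwashing water, 2019 US$.

    Volume is ``water_lpd x household_size x 365 / 1000`` m3/year, priced at
    the piped/non-piped blend of unit costs (already in 2019 US$ per m3).
    """
    volume_m3 = params.water_lpd * cs.household_size * 365.0 / 1000.0
    unit = cs.piped_share * cs.piped_unit_cost + (1.0 - cs.piped_share) * cs.nonpiped_unit_cost
    return volume_m3 * unit


# ---------------------------------------------------------------------------
# CSV I/O

PRICE_CSV_COLUMNS = [
    "category",
    "amount",
    "currency",
    "price_year",
    "country_code",
    "scope",
    "source_id",
]


def load_price_points(path) -> list[PricePoint]:
    df = pd.read_csv(path)
    missing = [c for c in PRICE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"price table is missing required columns: {missing}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                PricePoint(
                    category=str(row["category"]),
                    amount=float(row["amount"]),
                    currency=str(row["currency"]),
                    price_year=int(row["price_year"]),
                    country_code=str(row["country_code"]),
                    scope=str(row["scope"]),
                    source_id=str(row["source_id"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"price table row {idx}: {exc}") from exc
    return out


def price_points_frame(points: Iterable[PricePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": p.category,
                "amount": p.amount,
                "currency": p.currency,
                "price_year": p.price_year,
                "country_code": p.country_code,
                "scope": p.scope,
                "source_id": p.source_id,
            }
            for p in points
        ],
        columns=PRICE_CSV_COLUMNS,
    )


def load_economic_factors(path) -> dict[str, EconomicFactors]:
    """Read the long-form factors CSV (one row per country x year)."""
    df = pd.read_csv(path)
    required = ["country_code", "year", "deflator", "ppp_lcu_per_int_dollar", "fx_lcu_per_usd"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"factors table is missing required columns: {missing}")
    out: dict[str, EconomicFactors] = {}
    for code, grp in df.groupby("country_code", sort=True):
        years = grp["year"].astype(int)
        deflator = dict(zip(years, grp["deflator"].astype(float)))
        fx = dict(zip(years, grp["fx_lcu_per_usd"].astype(float)))
        ref = grp[years == REFERENCE_YEAR]
        if ref.empty:
            raise ValueError(f"{code}: factors must include a 2019 row")
        out[str(code)] = EconomicFactors(
            country_code=str(code),
            deflator=deflator,
            ppp_lcu_per_int_dollar=float(ref["ppp_lcu_per_int_dollar"].iloc[0]),
            fx_lcu_per_usd=fx,
        )
    return out


def economic_factors_frame(factors: Mapping[str, EconomicFactors]) -> pd.DataFrame:
    rows = []
    for code in sorted(factors):
        ef = factors[code]
        for year in sorted(ef.deflator):
            rows.append(
                {
                    "country_code": code,
                    "year": year,
                    "deflator": ef.deflator[year],
                    "ppp_lcu_per_int_dollar": ef.ppp_lcu_per_int_dollar,
                    "fx_lcu_per_usd": ef.fx_lcu_per_usd.get(year, ef.fx_2019),
                }
            )
    return pd.DataFrame(rows)
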