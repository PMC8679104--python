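"""Country-level quantities: service coverage, households and cohort scale-up.

One record per country x {urban, rural} stratum carries the hygiene service
breakdown (no facility / limited / basic), the split of the limited group by
limiting factor (soap missing / water missing / both), household size,
population projections and water-supply attributes.  Households are derived
as population / household size, assuming one handwashing facility per
household.  Scale-up reaches one cohort of unserved households per year: the
cumulative served fraction after implementation year ``t`` is ``t/horizon``,
applied to the year-``t`` unserved stock, so cohort sizes are the successive
differences and reduce to exactly equal cohorts under constant population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .params import SETTINGS, CostParameters

_PROP_TOL = 1e-9
#: Allowed provenance states.  ``missing`` is a transient pre-imputation
#: state; a table entering the cost engine must not contain it.
PROVENANCE = ("observed", "earlier_year", "ldc_average", "missing")


@dataclass(frozen=True)
class ServiceBreakdown:
    """Hygiene service levels and the split of the limited group.

    ``no_facility + limited + basic`` and the three limited-group shares
    must each sum to one.
    """

    no_facility: float
    limited: float
    basic: float
    limited_soap_only: float
    limited_water_only: float
    limited_both_missing: float

    def __post_init__(self) -> None:
        for name in (
            "no_facility",
            "limited",
            "basic",
            "limited_soap_only",
            "limited_water_only",
            "limited_both_missing",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        s = self.no_facility + self.limited + self.basic
        if abs(s - 1.0) > _PROP_TOL:
            raise ValueError(f"service shares must sum to 1 (got {s:.12f})")
        s = self.limited_soap_only + self.limited_water_only + self.limited_both_missing
        if abs(s - 1.0) > _PROP_TOL:
            raise ValueError(f"limited-factor shares must sum to 1 (got {s:.12f})")


@dataclass(frozen=True)
class CountrySetting:
    """One country x setting stratum."""

    country_code: str
    setting: str
    household_size: float
    population: Mapping[int, float]
    service: ServiceBreakdown | None
    piped_share: float
    piped_unit_cost: float
    nonpiped_unit_cost: float
    data_provenance: str = "observed"

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}, got {self.setting!r}")
        if not 1.0 < self.household_size < 15.0:
            raise ValueError(
                f"{self.country_code}/{self.setting}: household_size must be in (1, 15), "
                f"got {self.household_size}"
            )
        for year, pop in self.population.items():
            if not pop > 0:
                raise ValueError(
                    f"{self.country_code}/{self.setting}: population({year}) must be "
                    f"strictly positive, got {pop}"
                )
        if not 0.0 <= self.piped_share <= 1.0:
            raise ValueError(f"piped_share must be in [0, 1], got {self.piped_share}")
        for name in ("piped_unit_cost", "nonpiped_unit_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.data_provenance not in PROVENANCE:
            raise ValueError(f"unknown provenance {self.data_provenance!r}")
        if self.service is None and self.data_provenance != "missing":
            raise ValueError(
                f"{self.country_code}/{self.setting}: no service breakdown but "
                f"provenance is {self.data_provenance!r}"
            )

    def households(self, year: int) -> float:
        """Total households in ``year`` (fractional counts kept internally)."""
        if year not in self.population:
            raise KeyError(
                f"{self.country_code}/{self.setting}: year {year} outside the "
                f"population projections"
            )
        return self.population[year] / self.household_size


@dataclass(frozen=True)
class QuantityTable:
    """Validated collection of country x setting records."""

    records: tuple[CountrySetting, ...]
    base_year: int = 2021
    horizon: int = 10

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        keys = [(r.country_code, r.setting) for r in self.records]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (country, setting) records: {dupes}")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def countries(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.country_code, None)
        return tuple(seen)

    def get(self, country_code: str, setting: str) -> CountrySetting:
        for r in self.records:
            if r.country_code == country_code and r.setting == setting:
                return r
        raise KeyError((country_code, setting))


# ---------------------------------------------------------------------------
# CSV I/O

_SHARE_COLS = (
    "share_no_facility",
    "share_limited",
    "share_basic",
    "limited_soap_only",
    "limited_water_only",
    "limited_both",
)


def _pop_cols(base_year: int, horizon: int) -> list[str]:
    return [f"pop_{y}" for y in range(base_year, base_year + horizon)]


def load_country_table(path, base_year: int = 2021, horizon: int = 10) -> QuantityTable:
    """Load and validate a country table CSV.

    Rows with empty service-share cells are admitted only with provenance
    ``missing`` and must be completed by :func:`impute_missing` before
    costing.  Any invariant violation is reported with the offending row.
    """
    df = pd.read_csv(path)
    required = (
        ["country_code", "setting", "household_size"]
        + _pop_cols(base_year, horizon)
        + list(_SHARE_COLS)
        + ["piped_share", "piped_unit_cost", "nonpiped_unit_cost", "provenance"]
    )
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"country table is missing required columns: {missing_cols}")

    records: list[CountrySetting] = []
    for idx, row in df.iterrows():
        label = f"row {idx} ({row['country_code']}/{row['setting']})"
        try:
            shares = [row[c] for c in _SHARE_COLS]
            if all(pd.isna(v) for v in shares):
                service = None
                provenance = "missing"
            else:
                service = ServiceBreakdown(
                    no_facility=float(row["share_no_facility"]),
                    limited=float(row["share_limited"]),
                    basic=float(row["share_basic"]),
                    limited_soap_only=float(row["limited_soap_only"]),
                    limited_water_only=float(row["limited_water_only"]),
                    limited_both_missing=float(row["limited_both"]),
                )
                provenance = str(row["provenance"])
            records.append(
                CountrySetting(
                    country_code=str(row["country_code"]),
                    setting=str(row["setting"]),
                    household_size=float(row["household_size"]),
                    population={
                        y: float(row[f"pop_{y}"]) for y in range(base_year, base_year + horizon)
                    },
                    service=service,
                    piped_share=float(row["piped_share"]),
                    piped_unit_cost=float(row["piped_unit_cost"]),
                    nonpiped_unit_cost=float(row["nonpiped_unit_cost"]),
                    data_provenance=provenance,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{label}: {exc}") from exc
    return QuantityTable(records=tuple(records), base_year=base_year, horizon=horizon)


def country_table_frame(table: QuantityTable) -> pd.DataFrame:
    """Serialise a table back to the CSV column layout."""
    rows = []
    for r in table:
        row: dict[str, object] = {
            "country_code": r.country_code,
            "setting": r.setting,
            "household_size": r.household_size,
        }
        for y in range(table.base_year, table.base_year + table.horizon):
            row[f"pop_{y}"] = r.population[y]
        sb = r.service
        row.update(
            share_no_facility=sb.no_facility if sb else np.nan,
            share_limited=sb.limited if sb else np.nan,
            share_basic=sb.basic if sb else np.nan,
            limited_soap_only=sb.limited_soap_only if sb else np.nan,
            limited_water_only=sb.limited_water_only if sb else np.nan,
            limited_both=sb.limited_both_missing if sb else np.nan,
            piped_share=r.piped_share,
            piped_unit_cost=r.piped_unit_cost,
            nonpiped_unit_cost=r.nonpiped_unit_cost,
            provenance=r.data_provenance,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Imputation

def impute_missing(
    table: QuantityTable,
    ldc_average: ServiceBreakdown,
    earlier: Mapping[tuple[str, str], ServiceBreakdown] | None = None,
) -> QuantityTable:
    """Complete records lacking a service breakdown.

    An earlier-year estimate is used where available (provenance
    ``earlier_year``); otherwise the LDC average is applied (provenance
    ``ldc_average``).  Observed records pass through untouched, so the
    operation is idempotent.
    """
    earlier = earlier or {}
    out = []
    for r in table:
        if r.service is not None:
            out.append(r)
            continue
        key = (r.country_code, r.setting)
        if key in earlier:
            out.append(replace(r, service=earlier[key], data_provenance="earlier_year"))
        else:
            out.append(replace(r, service=ldc_average, data_provenance="ldc_average"))
    return QuantityTable(records=tuple(out), base_year=table.base_year, horizon=table.horizon)


# ---------------------------------------------------------------------------
# Targeted households and the cohort schedule

def _require_service(cs: CountrySetting) -> ServiceBreakdown:
    if cs.service is None:
        raise ValueError(
            f"{cs.country_code}/{cs.setting}: service breakdown missing; "
            f"run impute_missing first"
        )
    return cs.service


def unserved_households(cs: CountrySetting, year: int) -> float:
    """Households with no handwashing facility in ``year``."""
    return cs.households(year) * _require_service(cs).no_facility


def all_households(cs: CountrySetting, year: int) -> float:
    """Every household in the stratum, regardless of service level."""
    return cs.households(year)


def limited_households_by_factor(cs: CountrySetting, year: int) -> dict[str, float]:
    """Limited-service households split by limiting factor.

    Returns counts for ``soap_only`` (facility present, soap missing),
    ``water_only`` and ``both_missing``; they sum to the limited-service
    household stock.
    """
    sb = _require_service(cs)
    limited = cs.households(year) * sb.limited
    return {
        "soap_only": limited * sb.limited_soap_only,
        "water_only": limited * sb.limited_water_only,
        "both_missing": limited * sb.limited_both_missing,
    }


def target_share(cs: CountrySetting, target: str) -> float:
    """Share of households in a named target stock."""
    sb = _require_service(cs)
    shares = {
        "no_facility": sb.no_facility,
        "all": 1.0,
        "limited_soap_only": sb.limited * sb.limited_soap_only,
        "limited_water_only": sb.limited * sb.limited_water_only,
        "limited_both_missing": sb.limited * sb.limited_both_missing,
    }
    try:
        return shares[target]
    except KeyError:
        raise ValueError(f"unknown target stock {target!r}") from None


def cohort_increment(
    cs: CountrySetting,
    year_index: int,
    params: CostParameters,
    target: str = "no_facility",
) -> float:
    """Households newly reached in implementation year ``year_index`` (1-based).

    The cumulative served fraction after year ``t`` is ``t/horizon`` of the
    year-``t`` target stock (computed from that year's population
    projection); increments are the successive differences, so they sum to
    the final-year stock and reduce to equal cohorts under constant
    population.
    """
    h = params.horizon
    if not 1 <= year_index <= h:
        raise ValueError(f"year_index must be in 1..{h}, got {year_index}")
    share = target_share(cs, target)

    def served(t: int) -> float:
        if t == 0:
            return 0.0
        return cs.households(params.base_year + t - 1) * share * t / h

    return served(year_index) - served(year_index - 1)


def cohort_increments(
    cs: CountrySetting,
    params: CostParameters,
    target: str = "no_facility",
) -> np.ndarray:
    """Vector of newly-reached households for every implementation year."""
    return np.array(
        [cohort_increment(cs, t, params, target=target) for t in range(1, params.horizon + 1)]
    )


def aggregate_unserved(table: QuantityTable, year: int) -> float:
    """Total no-facility households across all strata in ``year``."""
    return float(sum(unserved_households(r, year) for r in table))
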