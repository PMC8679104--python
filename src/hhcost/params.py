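"""Model constants and scenario switches.

The costing model books six cost categories per household cohort:

* ``formative`` — design-phase research before the promotion campaign
  (software capital, one-off per country, 1-year useful life);
* ``promotion`` — the behaviour-change campaign itself (software capital,
  repeated in full at the end of its useful life);
* ``hwf`` — the handwashing facility, a purpose-built 20 L drum with tap,
  basin and stand (hardware capital, repeat purchase at end of life);
* ``topup`` — annual reinforcement promotion at a fraction of the initial
  campaign cost (software capital maintenance, treated as recurrent);
* ``soap`` — annual household expenditure on soap for handwashing;
* ``water`` — annual cost of water used for handwashing.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Cost categories in reporting order.
CATEGORIES: tuple[str, ...] = ("formative", "promotion", "topup", "hwf", "soap", "water")

#: Capital vs recurrent split used for the capital-share summary.  Top-up
#: promotion is capital *maintenance* and counts as recurrent.
CAPITAL_CATEGORIES = frozenset({"formative", "promotion", "hwf"})
RECURRENT_CATEGORIES = frozenset({"topup", "soap", "water"})

#: Price-datapoint categories (raw study prices) and the cost category each
#: one prices.  Which promotion datapoint category applies depends on the
#: scenario's promotion mode; top-up carries no price of its own (it is a
#: fraction of the promotion price).
PRICE_CATEGORIES: tuple[str, ...] = (
    "promotion_base",
    "promotion_alternative",
    "hwf",
    "hwf_homemade",
    "soap_annual",
    "formative_research",
)

PROMOTION_MODES = ("base", "alternative")
PROMOTION_TARGETS = ("no_facility_only", "whole_population")
SETTINGS = ("urban", "rural")


@dataclass(frozen=True)
class CostParameters:
    """Global model constants.

    Parameters
    ----------
    discount_rate
        Annual discount rate applied to all costs (base case 3 %).
    horizon
        Length of the scale-up period in years; one cohort of unserved
        households is reached per year, so the cumulative served fraction
        after year ``t`` is ``t / horizon``.
    base_year
        Calendar year of the first implementation year.
    promo_life, hwf_life, formative_life
        Useful lives in years.  Promotion and the facility are repeated in
        full when their life expires within the horizon; formative research
        is a one-off.
    topup_fraction
        Annual top-up promotion cost as a fraction of the initial campaign
        cost.
    water_lpd
        Water used for handwashing, litres per person per day.
    """

    discount_rate: float = 0.03
    horizon: int = 10
    base_year: int = 2021
    promo_life: int = 5
    hwf_life: int = 5
    formative_life: int = 1
    topup_fraction: float = 0.25
    water_lpd: float = 1.5

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError(f"discount_rate must be >= 0, got {self.discount_rate}")
        if self.horizon < 1:
            raise ValueError(f"horizon must be >= 1, got {self.horizon}")
        for name in ("promo_life", "hwf_life", "formative_life"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.topup_fraction <= 1.0:
            raise ValueError(f"topup_fraction must be in [0, 1], got {self.topup_fraction}")
        if self.water_lpd < 0:
            raise ValueError(f"water_lpd must be >= 0, got {self.water_lpd}")

    @property
    def years(self) -> range:
        """Calendar years covered by the horizon."""
        return range(self.base_year, self.base_year + self.horizon)


@dataclass(frozen=True)
class ScenarioSpec:
    """Scenario switches for a deterministic model run.

    ``promotion_mode='alternative'`` prices promotion (and hence top-up)
    from the lower-cost campaign excluding one-to-one activities.
    ``promotion_target='whole_population'`` targets promotion and top-up at
    every household rather than only those with no handwashing facility.
    ``include_limited_supplies`` adds soap and/or water costs for households
    with a facility but missing soap and/or water, according to the limiting
    factor.  ``economies_of_scale`` applies the declining unit-price
    schedule to promotion, top-up, facility and soap purchases.
    """

    promotion_mode: str = "base"
    promotion_target: str = "no_facility_only"
    include_limited_supplies: bool = False
    economies_of_scale: bool = False

    def __post_init__(self) -> None:
        if self.promotion_mode not in PROMOTION_MODES:
            raise ValueError(f"promotion_mode must be one of {PROMOTION_MODES}")
        if self.promotion_target not in PROMOTION_TARGETS:
            raise ValueError(f"promotion_target must be one of {PROMOTION_TARGETS}")

    @property
    def promotion_price_category(self) -> str:
        return "promotion_base" if self.promotion_mode == "base" else "promotion_alternative"
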