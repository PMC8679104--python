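"""Monte Carlo propagation of price uncertainty.

Quantities are held fixed; each iteration draws one value per sampled price
category from its gamma prior (moment-matched to the pooled I$ mean and SE)
and re-evaluates the full cost model.  A single global draw per category is
applied to every country — the uncertain quantity is the pooled I$ mean
itself, so draws are perfectly correlated across countries; independent
country-level draws would understate total-cost uncertainty.  Top-up
inherits the promotion draw (it is defined as a fraction of the promotion
price) and the constructed water price is held fixed by default.
Uncertainty intervals are empirical percentiles of the draw totals (linear
interpolation between order statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .costs import PreparedModel
from .prices import PriceDistribution

#: Cost categories sampled by default (water is constructed, not pooled,
#: and is held fixed unless ``water_cv`` is set).
DEFAULT_SAMPLED = frozenset({"promotion", "hwf", "soap", "formative"})


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo settings.

    ``water_cv``, if set, samples a gamma multiplier with mean 1 and the
    given coefficient of variation for the water price (off by default: the
    water price is built from tariff assumptions, not sampled datapoints).
    """

    n_draws: int = 1000
    seed: int = 0
    interval: tuple[float, float] = (2.5, 97.5)
    sampled_categories: frozenset[str] = DEFAULT_SAMPLED
    water_cv: float | None = None

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ValueError(f"n_draws must be >= 2, got {self.n_draws}")
        lo, hi = self.interval
        if not (0.0 < lo < hi < 100.0):
            raise ValueError(f"interval percentiles must satisfy 0 < lo < hi < 100, got {self.interval}")
        unknown = set(self.sampled_categories) - {"promotion", "hwf", "soap", "formative", "water"}
        if unknown:
            raise ValueError(f"cannot sample categories {sorted(unknown)}")


@dataclass(frozen=True)
class McResult:
    """Draw totals and percentile intervals for the reported aggregates."""

    draws: pd.DataFrame  # columns: draw, total, promotion_only, facilities_supplies
    point_estimate: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    seed_used: int
    n_draws: int

    @property
    def ci_lower(self) -> float:
        return self.intervals["total"][0]

    @property
    def ci_upper(self) -> float:
        return self.intervals["total"][1]


def sample_category_prices(
    dists: Mapping[str, PriceDistribution],
    rng: np.random.Generator,
    n_draws: int,
) -> dict[str, np.ndarray]:
    """Gamma draws of the pooled I$ mean, one vector per category."""
    out = {}
    for cat, d in dists.items():
        if not (d.gamma_shape > 0 and d.gamma_scale > 0):
            raise ValueError(f"{cat}: invalid gamma parameters")
        out[cat] = rng.gamma(shape=d.gamma_shape, scale=d.gamma_scale, size=n_draws)
    return out


def run_monte_carlo(model: PreparedModel, config: McConfig) -> McResult:
    """Propagate price uncertainty through a prepared cost model.

    Returns draw-level totals for the overall, promotion-only and
    facilities-and-supplies aggregates, the deterministic point estimate
    (never altered by the draws) and percentile uncertainty intervals.
    """
    rng = np.random.default_rng(config.seed)
    dists = model.dists
    promo_cat = model.scenario.promotion_price_category
    sample_dists: dict[str, PriceDistribution] = {}
    if "promotion" in config.sampled_categories:
        sample_dists["promotion"] = dists[promo_cat]
    if "hwf" in config.sampled_categories:
        sample_dists["hwf"] = dists["hwf"]
    if "soap" in config.sampled_categories:
        sample_dists["soap"] = dists["soap_annual"]
    if "formative" in config.sampled_categories:
        sample_dists["formative"] = dists["formative_research"]

    draws_by_cat = sample_category_prices(sample_dists, rng, config.n_draws)
    if config.water_cv is not None and "water" in config.sampled_categories:
        shape = 1.0 / config.water_cv**2
        water_scale = rng.gamma(shape=shape, scale=1.0 / shape, size=config.n_draws)
    else:
        water_scale = np.ones(config.n_draws)

    records = []
    for i in range(config.n_draws):
        means = {cat: float(v[i]) for cat, v in draws_by_cat.items()}
        try:
            totals = model.evaluate(means, water_scale=float(water_scale[i]))
        except Exception as exc:  # pragma: no cover - contract: abort with context
            raise RuntimeError(
                f"model evaluation failed on draw {i} (seed {config.seed}): {exc}"
            ) from exc
        record = {
            "draw": i,
            "total": totals["total"],
            "promotion_only": totals["promotion_only"],
            "facilities_supplies": totals["facilities_supplies"],
        }
        for cat in ("formative", "promotion", "topup", "hwf", "soap", "water"):
            record[cat] = totals[cat]
        records.append(record)
    draws = pd.DataFrame(records)

    point = model.evaluate()
    point_estimate = {
        k: point[k] for k in ("total", "promotion_only", "facilities_supplies")
    }
    lo, hi = config.interval
    interval_cols = (
        "total", "promotion_only", "facilities_supplies",
        "formative", "promotion", "topup", "hwf", "soap", "water",
    )
    intervals = {
        col: (
            float(np.percentile(draws[col], lo)),
            float(np.percentile(draws[col], hi)),
        )
        for col in interval_cols
    }
    return McResult(
        draws=draws,
        point_estimate=point_estimate,
        intervals=intervals,
        seed_used=config.seed,
        n_draws=config.n_draws,
    )
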