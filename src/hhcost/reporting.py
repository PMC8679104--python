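"""Presentation of aggregated results.

Renders the summary object into report files: category totals with shares
and uncertainty intervals, the year x category cost matrix, and a headline
block (10-year total, promotion-only and facilities-and-supplies totals in
billions to one decimal, per-head and per-household figures).  Rendering is
a pure function of the summary (and optional Monte Carlo result): it never
recomputes the model.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .params import CATEGORIES
from .uncertainty import McResult


def billions(x: float) -> float:
    """US$ billions to one decimal (the paper-style headline rounding)."""
    return round(x / 1e9, 1)


def millions_3sf(x: float) -> float:
    """US$ millions to three significant figures."""
    m = x / 1e6
    if m == 0:
        return 0.0
    return float(np.format_float_positional(m, precision=3, fractional=False))


def headline_block(summary: Mapping, mc: McResult | None = None) -> dict:
    """The headline numbers, rounded for presentation."""
    block = {
        "total_10yr_usd_billion": billions(summary["total_usd2019"]),
        "promotion_only_usd_billion": billions(summary["promotion_only_total_usd2019"]),
        "facilities_supplies_usd_billion": billions(
            summary["facilities_supplies_total_usd2019"]
        ),
        "capital_share_pct": summary["capital_share_pct"],
        "category_shares_pct": dict(summary["category_shares_pct"]),
        "category_average_annual_usd_million": {
            c: millions_3sf(v)
            for c, v in summary["category_average_annual_usd2019"].items()
        },
    }
    if "per_head" in summary:
        ph = summary["per_head"]
        block["per_head_annual_usd"] = {
            "total": round(ph["annual_total_usd2019"], 2),
            "promotion": round(ph["annual_promotion_usd2019"], 2),
            "facilities_supplies": round(ph["annual_facilities_supplies_usd2019"], 2),
        }
    if "per_household_usd2019" in summary:
        block["per_household_usd"] = {
            k: round(v, 1) for k, v in summary["per_household_usd2019"].items()
        }
    if mc is not None:
        block["uncertainty_interval_usd_billion"] = {
            "total": [billions(mc.intervals["total"][0]), billions(mc.intervals["total"][1])],
            "promotion_only": [
                billions(mc.intervals["promotion_only"][0]),
                billions(mc.intervals["promotion_only"][1]),
            ],
            "facilities_supplies": [
                billions(mc.intervals["facilities_supplies"][0]),
                billions(mc.intervals["facilities_supplies"][1]),
            ],
        }
    return block


def category_totals_frame(summary: Mapping, mc: McResult | None = None) -> pd.DataFrame:
    """Category totals with shares and, when available, 95 % intervals."""
    rows = []
    for cat in CATEGORIES:
        row = {
            "category": cat,
            "total_usd2019": summary["category_totals_usd2019"][cat],
            "average_annual_usd2019": summary["category_average_annual_usd2019"][cat],
            "share_pct": summary["category_shares_pct"][cat],
        }
        if mc is not None and cat in mc.intervals:
            row["ci_lower_usd2019"], row["ci_upper_usd2019"] = mc.intervals[cat]
        rows.append(row)
    return pd.DataFrame(rows)


def by_year_frame(summary: Mapping, base_year: int = 2021) -> pd.DataFrame:
    """Year x category matrix of discounted costs, with annual totals."""
    data = {cat: summary["by_year_usd2019"][cat] for cat in CATEGORIES}
    df = pd.DataFrame(data)
    df.insert(0, "year", [base_year + t for t in range(len(df))])
    df["annual_total_usd2019"] = df[list(CATEGORIES)].sum(axis=1)
    return df


def render_summary(
    summary: Mapping,
    out_dir,
    mc: McResult | None = None,
    base_year: int = 2021,
) -> dict[str, Path]:
    """Write summary.json, category_totals.csv and by_year.csv to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = dict(summary)
    doc["headline"] = headline_block(summary, mc)
    if mc is not None:
        doc["monte_carlo"] = {
            "n_draws": mc.n_draws,
            "seed": mc.seed_used,
            "point_estimate_usd2019": mc.point_estimate,
            "intervals_usd2019": {k: list(v) for k, v in mc.intervals.items()},
        }
    paths = {}
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(doc, indent=2, sort_keys=True))
    paths["category_totals"] = out / "category_totals.csv"
    category_totals_frame(summary, mc).to_csv(paths["category_totals"], index=False)
    paths["by_year"] = out / "by_year.csv"
    by_year_frame(summary, base_year).to_csv(paths["by_year"], index=False)
    return paths
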