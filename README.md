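# hhcost

A costing model for **universal basic hand hygiene in household settings**
across the least developed countries (LDCs). Roughly 6 in 10 people in LDCs
lack a handwashing facility (HWF) with soap and water at home; planners need
an order-of-magnitude price tag for closing that gap. `hhcost` estimates the
10-year economic cost of reaching every household that has no facility, from
a societal perspective, by combining country-level *quantities* of unserved
households with standardised *prices* for the inputs of a behaviour-change
programme.

## The model

For country *c*, stratum *g* ∈ {urban, rural} and implementation year
*t* = 1…10, the targeted household stock is

    H_cg(t) = P_cg(t) / n_cg × s_cg

where *P* is the medium-variant population projection, *n* the average
household size and *s* the share of households with no HWF. Scale-up reaches
one cohort per year: the cumulative served fraction after year *t* is *t*/10
of the year-*t* stock, so cohort sizes are successive differences and are
exactly equal under constant population. Each cohort incurs six cost
categories: formative research (one-off, country level), a promotion
campaign (5-year useful life, repeated in full), an HWF (a purpose-built
20 L drum with tap and stand, 5-year life, repeat purchase), annual top-up
promotion at 25 % of the campaign price, and recurrent soap and water.
Costs are discounted at 3 %/year to year 1 (exponent *t* − 1).

Raw price datapoints from field studies are standardised as

    I$ = amount_LCU × deflator(2019)/deflator(y) ÷ PPP

(US$-denominated points are first moved into local currency at the year-*y*
exchange rate), pooled per category into a mean and standard error in 2019
international dollars, and re-localised to 2019 US$ per country via the
country's PPP/exchange-rate ratio. Price uncertainty is propagated by Monte
Carlo: each of 1000 iterations draws the pooled mean of each sampled
category from a gamma prior moment-matched to (mean, SE) — one global draw
per category, perfectly correlated across countries — and the 95 %
uncertainty interval is the 2.5th–97.5th percentile of the draw totals.
One-way deterministic scenarios (price CI bounds, discount rate, useful
lives, a home-made facility, an economies-of-scale price schedule, a
promotion campaign without one-to-one visits) feed a tornado table.

Because the real input tables (JMP coverage estimates, DHS household sizes,
UN projections, World Bank deflators and the study price tables) are not
bundled, the package ships a synthetic-data generator that emulates their
statistical structure, calibrated to published per-household US$ price
medians (promotion 33.9, HWF 14.8, soap 14.8/year, alternative promotion
19.4, home-made HWF 1.2). The frozen 46-country fixture `reference-46`
makes every analysis reproducible offline.

## Worked example

```python
from hhcost import build_inputs, run_deterministic, run_probabilistic, McConfig
from hhcost.reporting import headline_block
from hhcost.synthetic import reference_fixture

table, points, factors = reference_fixture()      # 46 countries x 2 strata
inputs = build_inputs(table, list(points), factors)
streams, summary = run_deterministic(inputs)
print(headline_block(summary))
mc = run_probabilistic(inputs, McConfig(n_draws=1000, seed=2021))
print([round(v / 1e9, 2) for v in mc.intervals["total"]])
```

prints (reference fixture, 3 % discounting, 2021–2030):

```
{'total_10yr_usd_billion': 12.6,
 'promotion_only_usd_billion': 4.9,
 'facilities_supplies_usd_billion': 7.8,
 'capital_share_pct': 35,
 'category_shares_pct': {'formative': 0, 'promotion': 24, 'topup': 15,
                         'hwf': 11, 'soap': 37, 'water': 14},
 'per_head_annual_usd': {'total': 1.24, 'promotion': 0.47,
                         'facilities_supplies': 0.76},
 'per_household_usd': {'promotion': 34.4, 'hwf': 16.3,
                       'soap_annual': 15.3, 'water_annual': 4.7}, ...}
[11.47, 13.8]
```

i.e. a 10-year total of US$12.6 billion (95 % UI 11.5–13.8), of which
US$4.9 billion is promotion (formative research, campaigns and top-up) and
US$7.8 billion facilities and supplies; soap is the largest single category
(37 %), and promotion costs about US$0.47 per head of population per year.

## Analysis scripts

The numbered drivers under `analysis/` run the study end-to-end on the
reference fixture and write tables under `results/`:

1. `01_generate_inputs.py` — synthetic country/price/factor CSVs
2. `02_pool_prices.py` — standardised, pooled price distributions
3. `03_base_case.py` — deterministic base case (summary, totals, by-year)
4. `04_monte_carlo.py` — 1000-draw uncertainty intervals
5. `05_sensitivity.py` — tornado table over the scenario catalogue
6. `06_scenario_variants.py` — limited-service supplies and
   whole-population promotion variants

A `hhcost` CLI exposes the same pipeline over CSV inputs
(`gen-data`, `prices`, `run`, `mc`, `sens`, `report`); see `hhcost --help`.

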