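# Methods

## Scope and perspective

`hhcost` estimates the economic cost, from a societal perspective, of giving
every household that currently has no handwashing facility (HWF) a basic
hand hygiene service — a facility with soap and water at home — over a
10-year horizon (2021–2030). It is a resource-requirement model: the cost
of *reaching* all target households is estimated, and intervention
effectiveness, uptake and adherence are deliberately outside scope, as are
disease-burden attribution, cost-effectiveness and the capital cost of new
water supplies. Quantities and prices are analysed per country separately
for urban and rural strata and aggregated afterwards.

## Quantities and the cohort schedule

The targeted stock in a stratum is `population(year) / household_size ×
share_no_facility`, assuming one facility per household. Coverage shares
are held at their baseline values for all years (no secular trend is
projected); populations follow year-specific projections.

Scale-up reaches ten equal cohorts of unserved households, one per year.
Under population growth "equal cohorts" and "year-specific stocks" cannot
both hold exactly, so the model fixes the cumulative served fraction after
implementation year *t* at `t / horizon` of the **year-t** stock; cohort
sizes are the successive differences. This reduces to exactly equal cohorts
under constant population, and the increments provably sum to the final
year's stock (tested as an invariant). Sizing cohorts on year-specific
rather than base-year stocks was a genuinely open choice; the year-specific
reading keeps the programme aligned with the population actually present
when each cohort is served. Fractional household counts are kept throughout
and rounded only at reporting, avoiding order-dependent rounding error
across the 92 strata.

Households with a *limited* service (facility present, but soap and/or
water missing at the time of survey) are split by limiting factor — soap
only, water only, both — and, in the corresponding scenario, receive only
the supplies they lack (soap, water, or both). These supply-only cohorts
follow the same ten-year schedule as the headline population, for
consistency of treatment.

Missing service breakdowns are imputed in two steps: an earlier-year
estimate where one is available, otherwise the average across all modelled
countries; the record's provenance field tracks which policy filled it, and
the operation is idempotent.

## Prices

Raw datapoints are standardised to 2019 international dollars (I$):
amounts reported in US$ are first converted to the study country's local
currency at the price-year market exchange rate (inflation must be applied
in the economy where the price arose — this currency path is a modelling
choice, since source studies do not state one), then inflated with the
country's GDP deflator to 2019, then divided by the PPP conversion factor.
Pooling happens in I$ because a US$ mean is biased by purchasing power:
I$42 of soap converts to about US$10 in a country with a price level of
0.24 and US$18 at 0.43.

Per category the pooled estimate is the sample mean with standard error
`SD/√n`; the SE of the mean (not the sample SD) parameterises the
uncertainty prior, reflecting that the uncertain quantity is the pooled
mean itself. Price data are right-skewed, so the prior is a gamma
distribution moment-matched as `shape = (mean/SE)²`, `scale = SE²/mean`
(round-trips to 1e-10; verified by property test). A category with a
single datapoint takes a fallback SE of `mean × median CV` across the
multi-point categories (default CV 0.25 at the unit level); identical
points yield a degenerate SE of zero and are rejected with a pointer to a
minimum-SE floor rather than silently producing a spike prior.

Pooled I$ means are re-localised to 2019 US$ per country by the PPP/
exchange-rate ratio. The household water price is constructed, not pooled:
1.5 L/person/day × household size × 365, priced at the stratum's blend of
piped tariff and non-piped unit cost (both already in 2019 US$/m³).
Formative research goes through the same standardise–pool–localise path and
is booked once per country in year 1 (one-off, 1-year useful life, not
repeated).

## Cost accounting

Capital items (promotion campaign, facility) are booked in full in the year
purchased and repurchased at the end of their 5-year useful life within the
horizon; no residual value is credited at horizon end. An
equivalent-annual-cost utility (`equivalent_annual_cost`) is provided as an
alternative reporting mode for users who prefer annuitised capital, but the
base case uses full-cost booking: it is what makes per-year capital costs
flat across the scale-up (each year one cohort buys in) and it reproduces
the expected ratio of top-up to initial promotion spending.

Top-up promotion accrues at 25 % of the campaign price in every year of a
cohort's timeline *after* its start, except years in which the full
campaign is repeated — paying both in a repeat year would double-count.
Top-up is software capital maintenance and counts as **recurrent** in the
capital/recurrent split (capital = formative + promotion + facility).

Discounting uses start-of-year accrual: cost(t)/(1+r)^(t−1), so year-1
costs are undiscounted and a constant unit stream over 10 years at 3 % has
present value 8.786 (the annuity-due factor; asserted in tests). The base
discount rate is 3 %/year.

The economies-of-scale scenario multiplies the unit prices of promotion
(and top-up), facilities and soap by a declining schedule: reductions on
the year-1 price of 10 % in year 2, then 2-point decrements (8 %, 6 %,
4 %, 2 %) accumulating additively to 30 % from year 6 onward — multipliers
1.00, 0.90, 0.82, 0.76, 0.72, 0.70, 0.70…. Additive decrements (not
compounding) are used because the schedule is defined by its 30 % terminal
reduction.

## Uncertainty

Monte Carlo (default 1000 draws, seeded) varies prices only; quantities
have no published uncertainty and stay fixed. Each iteration draws one
value per sampled category (promotion, facility, soap, formative research)
from its gamma prior and applies it to **all** countries after
localisation: the uncertain quantity is the pooled I$ mean, so draws are
perfectly correlated across countries, and independent country-level noise
would understate total-cost uncertainty. Top-up inherits the promotion
draw. The constructed water price is held fixed by default; a `water_cv`
switch samples a mean-1 gamma multiplier for users who want it varied.
Intervals are empirical percentiles (linear interpolation between order
statistics, the numpy default).

Because localisation and costing are linear in each category's pooled
mean, the model is prepared once (quantity coefficients per category) and
each draw is an exact re-evaluation at the sampled means; equality with the
stream-by-stream model is asserted in the test suite rather than assumed.

## Deterministic sensitivity

The scenario catalogue ships as YAML data, not code: price means at their
95 % gamma CI bounds, discount rate 0 %/6 %, useful lives 3/7 years,
top-up fraction 12.5 %/50 %, a home-made facility at a flat US$1.2 per
household, economies of scale, and the alternative promotion campaign
(excluding one-to-one visits, priced from its own datapoint pool). The
low/high endpoint values for lives and the top-up fraction are the
package's own plausible ranges. Results are oriented (low ≤ high) and
sorted by absolute swing, the tornado ordering.

## Synthetic data

The generator emulates the study frame rather than any real country:
46 countries with log-normal populations summing to roughly a billion
people, urban shares of 20–45 %, growth of 1.5–3 %/year, household sizes
of 4–5.5 (urban) and 4.5–6.5 (rural), Dirichlet service breakdowns centred
on (0.18, 0.27, 0.55) urban and (0.38, 0.33, 0.29) rural so that roughly a
third of households lack a facility (tens of millions of unserved
households at LDC scale), limited splits centred on (0.47, 0.10, 0.43),
and price levels (PPP/FX) of 0.24–0.43. Deflators are smooth constant-
inflation series with base 2019 = 100; nominal exchange rates drift with
inflation.

Price datapoints are gamma draws (default CV 0.5, a moderate right skew)
whose sample median is rescaled exactly onto the target so that the
localised median across countries lands on the published per-household US$
anchors; with CV 0.5 the gamma mean sits ~9 % above its median, which is
why the mean-based localised prices sit slightly above the anchors (well
inside the 15 % calibration band checked in tests). Formative research is
calibrated on its US$ mean (US$100 000) instead of a median. Each point is
assigned a study country and year and back-converted into raw local
currency (or US$ for ~30 % of points), so the standardisation path is
genuinely exercised and inverts the construction. Datapoint counts follow
the source-study counts (14 promotion, 16 facility, 10 soap, 5 formative;
8 alternative-promotion and 6 home-made-facility points are the package's
own choices, since no counts are published for those subsets).

What passing tests on synthetic data do **not** show: agreement with any
real country's costs, urban/rural price differences (a single national
price per category is applied, as in the underlying evidence), coverage
trends, or the behaviour of the model under the real, much lumpier JMP
coverage distributions. They do show that the arithmetic, accounting rules,
uncertainty propagation and aggregation are correct and internally
consistent at realistic magnitudes.

## Numerical choices and problem sizes

Proportion invariants are enforced to 1e-9; conservation checks to 1e-9
relative; the gamma round-trip to 1e-10. Ties in the top-up/campaign cycle
resolve in favour of the campaign (no top-up in repeat years). Degenerate
inputs fail loudly: zero SEs, missing price categories, years outside the
projection range and invalid shares all raise with row- or
category-addressed messages. The test suite and the analysis scripts run
the full 46-country fixture (92 strata × 6 categories × 10 years) plus
small hand-built tables for oracle comparisons; Monte Carlo uses 1000
draws in the drivers and 100–2000 in tests, sizes at which the entire
suite completes in seconds on one CPU.

## Known limitations

- The cohort-sizing rule under growth is a reconstruction (the source
  model's exact household equation is unpublished); both it and the
  base-year alternative honour "equal cohorts" only under zero growth.
- Single national prices per category; no urban/rural price gradient.
- The water price is an assumption-built construct with no sampling
  distribution of its own.
- Annuitised capital reporting is available but not the base case; users
  comparing against ledgers that annuitise should use
  `equivalent_annual_cost`.
- No financing-source split (who pays), no front-loaded roll-out shapes,
  and no capital maintenance for facilities (short useful life, simple
  hardware).
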