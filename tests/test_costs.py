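"""Cost engine: profiles, discounting, aggregation and oracle equivalence."""

import numpy as np
import pytest

from hhcost import (
    CostParameters,
    CostStream,
    PreparedModel,
    QuantityTable,
    ScenarioSpec,
    aggregate_total,
    annual_water_price,
    cohort_cost_profile,
    country_cost_stream,
    discount_stream,
    equivalent_annual_cost,
    model_cost_streams,
    service_schedule,
)
from hhcost.costs import discount_factors, scale_economy_multipliers, streams_frame

from conftest import flat_factors, make_stratum

H = 10


def brute_force_stratum_costs(cs, prices, params, scenario=None):
    """Independent oracle: literal per-cohort, per-year enumeration.

    Re-derives the cost rules from first principles: cohort t gets t/h of
    the year-t stock minus what was already served; each cohort pays
    promotion at its start year and every 5th year after, top-up at 25 % in
    the other post-start years, a facility at start and every 5th year,
    soap and water annually from the start year.  Returns undiscounted
    category totals by year.
    """
    scenario = scenario or ScenarioSpec()
    h = params.horizon
    share = cs.service.no_facility

    def stock(t):
        return cs.population[params.base_year + t - 1] / cs.household_size * share

    out = {cat: np.zeros(h) for cat in ("promotion", "topup", "hwf", "soap", "water")}
    for s in range(1, h + 1):
        cohort = stock(s) * s / h - (stock(s - 1) * (s - 1) / h if s > 1 else 0.0)
        for t in range(s, h + 1):
            age = t - s
            if age % params.promo_life == 0:
                out["promotion"][t - 1] += cohort * prices["promotion"]
            else:
                out["topup"][t - 1] += cohort * params.topup_fraction * prices["promotion"]
            if age % params.hwf_life == 0:
                out["hwf"][t - 1] += cohort * prices["hwf"]
            out["soap"][t - 1] += cohort * prices["soap"]
            out["water"][t - 1] += cohort * prices["water"]
    return out


class TestSchedulesAndProfiles:
    def test_service_schedule(self):
        assert service_schedule(10) == pytest.approx(np.arange(1, 11) / 10)
        assert service_schedule(1) == pytest.approx([1.0])
        assert service_schedule(4) == pytest.approx([0.25, 0.5, 0.75, 1.0])
        with pytest.raises(ValueError):
            service_schedule(0)

    def test_promotion_repeats_at_end_of_life(self, params):
        prof = cohort_cost_profile("promotion", 3, params)
        assert list(np.nonzero(prof)[0] + 1) == [3, 8]
        assert prof[[2, 7]] == pytest.approx([1.0, 1.0])

    def test_topup_fills_non_campaign_years(self, params):
        prof = cohort_cost_profile("topup", 3, params)
        assert list(np.nonzero(prof)[0] + 1) == [4, 5, 6, 7, 9, 10]
        assert set(prof[np.nonzero(prof)]) == {0.25}

    def test_soap_runs_from_service_year(self, params):
        prof = cohort_cost_profile("soap", 9, params)
        assert list(np.nonzero(prof)[0] + 1) == [9, 10]
        assert prof[8:] == pytest.approx([1.0, 1.0])

    def test_unknown_category_and_bad_year(self, params):
        with pytest.raises(ValueError):
            cohort_cost_profile("laundry", 1, params)
        with pytest.raises(ValueError):
            cohort_cost_profile("soap", 11, params)
        with pytest.raises(ValueError, match="country-level"):
            cohort_cost_profile("formative", 1, params)

    def test_scale_economy_multipliers(self):
        mult = scale_economy_multipliers(10)
        assert mult[:6] == pytest.approx([1.00, 0.90, 0.82, 0.76, 0.72, 0.70])
        assert mult[6:] == pytest.approx([0.70] * 4)


class TestDiscounting:
    def test_zero_rate_is_identity(self):
        s = CostStream("AAA", "rural", "soap", np.ones(10), np.ones(10))
        assert discount_stream(s, 0.0).discounted_by_year == pytest.approx(np.ones(10))

    def test_year_two_at_three_percent(self):
        cost = np.zeros(10)
        cost[1] = 103.0
        s = CostStream("AAA", "rural", "soap", cost, cost)
        assert discount_stream(s, 0.03).discounted_by_year[1] == pytest.approx(100.0)

    def test_constant_stream_matches_annuity_due_closed_form(self):
        # sum of 1/(1.03)^(t-1), t=1..10 equals the annuity-due factor 8.786
        closed_form = (1 - 1.03**-10) / 0.03 * 1.03
        s = CostStream("AAA", "rural", "soap", np.ones(10), np.ones(10))
        total = discount_stream(s, 0.03).discounted_total
        assert total == pytest.approx(closed_form, rel=1e-12)
        assert total == pytest.approx(8.786, abs=5e-4)

    def test_negative_rate_rejected(self):
        s = CostStream("AAA", "rural", "soap", np.ones(10), np.ones(10))
        with pytest.raises(ValueError):
            discount_stream(s, -0.01)

    def test_equivalent_annual_cost(self):
        assert equivalent_annual_cost(100.0, 0.0, 5) == pytest.approx(20.0)
        eac = equivalent_annual_cost(100.0, 0.03, 5)
        # the EAC repays the outlay: discounted sum of 5 payments = 100
        pv = sum(eac / 1.03**t for t in range(1, 6))
        assert pv == pytest.approx(100.0, rel=1e-12)


class TestStreams:
    def test_single_cohort_promotion_repeats(self, params, scenario):
        # one cohort of 1,000 households served in year 1 (horizon-1 stock,
        # then held): promotion 30,000 at years 1 and 6 only
        cs = make_stratum(pop0=10_000.0 * 5, household_size=5, no_facility=1.0,
                          limited=0.0)
        prices = {"promotion": 30.0, "hwf": 19.0, "soap": 17.0, "water": 5.0}
        streams = {
            s.category: s for s in country_cost_stream(cs, prices, params, scenario)
        }
        promo = streams["promotion"].cost_by_year
        # each year adds a 1,000-household cohort; year 6 repeats cohort 1
        assert promo[0] == pytest.approx(30_000.0)
        assert promo[5] == pytest.approx(2 * 30_000.0)
        soap = streams["soap"].cost_by_year
        assert soap[0] == pytest.approx(17_000.0)
        assert soap[9] == pytest.approx(170_000.0)

    def test_missing_price_is_an_error(self, params, scenario, simple_stratum):
        with pytest.raises(ValueError, match="soap"):
            country_cost_stream(
                simple_stratum, {"promotion": 30.0, "hwf": 19.0, "water": 5.0},
                params, scenario,
            )

    def test_limited_supplies_split_rule(self, params):
        # 10,000 limited households, split 47/10/43: soap for soap-only +
        # both-missing (9,000), water for water-only + both-missing (5,300)
        p = CostParameters(horizon=1)
        cs1 = make_stratum(pop0=10_000.0 * 5 * 10, household_size=5.0,
                           no_facility=0.0, limited=0.1, horizon=1)
        scen = ScenarioSpec(include_limited_supplies=True)
        streams = {
            s.category: s
            for s in country_cost_stream(
                cs1, {"promotion": 30.0, "hwf": 19.0, "soap": 17.0, "water": 5.0},
                p, scen,
            )
        }
        assert streams["soap"].cost_by_year[0] == pytest.approx(17.0 * 9_000)
        assert streams["water"].cost_by_year[0] == pytest.approx(5.0 * 5_300)


class TestOracleEquivalence:
    @pytest.mark.parametrize("growth", [0.0, 0.02])
    @pytest.mark.parametrize("rate", [0.0, 0.03])
    def test_engine_matches_brute_force_enumeration(self, growth, rate):
        params = CostParameters(discount_rate=rate)
        scenario = ScenarioSpec()
        strata = [
            make_stratum(setting="urban", pop0=400_000, growth=growth, no_facility=0.25),
            make_stratum(setting="rural", pop0=900_000, growth=growth, no_facility=0.45,
                         household_size=6.0),
        ]
        prices = {"promotion": 33.9, "hwf": 14.8, "soap": 14.8, "water": 5.0}
        df = discount_factors(rate, params.horizon)
        for cs in strata:
            oracle = brute_force_stratum_costs(cs, prices, params)
            engine = {
                s.category: s for s in country_cost_stream(cs, prices, params, scenario)
            }
            for cat, expect in oracle.items():
                assert engine[cat].cost_by_year == pytest.approx(expect, rel=1e-10)
                assert engine[cat].discounted_by_year == pytest.approx(
                    expect * df, rel=1e-10
                )


class TestModelInvariants:
    def test_conservation_across_partitions(self, small_inputs):
        streams = model_cost_streams(
            small_inputs.table, small_inputs.dists, small_inputs.factors,
            small_inputs.params, small_inputs.scenario,
        )
        summary = aggregate_total(streams, small_inputs.params)
        total = summary["total_usd2019"]
        assert sum(summary["category_totals_usd2019"].values()) == pytest.approx(
            total, rel=1e-9
        )
        by_country = {}
        for s in streams:
            by_country[s.country_code] = by_country.get(s.country_code, 0.0) + s.discounted_total
        assert sum(by_country.values()) == pytest.approx(total, rel=1e-9)

    def test_capital_flat_then_repeats_under_constant_population(self):
        params = CostParameters(discount_rate=0.0)
        cs = make_stratum(pop0=1_000_000, growth=0.0)
        prices = {"promotion": 30.0, "hwf": 19.0, "soap": 17.0, "water": 5.0}
        streams = {
            s.category: s for s in country_cost_stream(cs, prices, params, ScenarioSpec())
        }
        promo = streams["promotion"].cost_by_year
        assert np.ptp(promo[:5]) == pytest.approx(0.0, abs=1e-9)
        assert promo[5:] == pytest.approx(2 * promo[:5], rel=1e-12)

    def test_recurrent_costs_nondecreasing(self, small_inputs):
        streams = model_cost_streams(
            small_inputs.table, small_inputs.dists, small_inputs.factors,
            small_inputs.params, small_inputs.scenario,
        )
        recurrent = np.zeros(small_inputs.params.horizon)
        for s in streams:
            if s.category in ("topup", "soap", "water"):
                recurrent += s.cost_by_year
        assert np.all(np.diff(recurrent) >= -1e-9)

    def test_scenario_monotonicity(self, small_inputs):
        def total(scenario):
            return PreparedModel(
                small_inputs.table, small_inputs.dists, small_inputs.factors,
                small_inputs.params, scenario,
            ).evaluate()["promotion"]

        base = total(ScenarioSpec())
        whole = total(ScenarioSpec(promotion_target="whole_population"))
        alt = total(ScenarioSpec(promotion_mode="alternative"))
        assert whole >= base
        assert small_inputs.dists["promotion_alternative"].i_mean < \
            small_inputs.dists["promotion_base"].i_mean
        assert alt <= base

    def test_prepared_model_matches_stream_model(self, small_inputs):
        streams = model_cost_streams(
            small_inputs.table, small_inputs.dists, small_inputs.factors,
            small_inputs.params, small_inputs.scenario,
        )
        summary = aggregate_total(streams, small_inputs.params)
        model = PreparedModel(
            small_inputs.table, small_inputs.dists, small_inputs.factors,
            small_inputs.params, small_inputs.scenario,
        )
        totals = model.evaluate()
        for cat, expect in summary["category_totals_usd2019"].items():
            assert totals[cat] == pytest.approx(expect, rel=1e-9), cat
        assert totals["total"] == pytest.approx(summary["total_usd2019"], rel=1e-9)


class TestAggregation:
    def test_empty_streams_rejected(self, params):
        with pytest.raises(ValueError):
            aggregate_total([], params)

    def test_single_category_share_is_100(self, params):
        s = CostStream("AAA", "rural", "soap", np.ones(10), np.ones(10))
        summary = aggregate_total([s], params)
        assert summary["category_shares_pct"]["soap"] == 100

    def test_printed_annual_averages_reproduce_headline_totals(self, params):
        """Feeding the printed per-category average annual costs through the
        aggregation layer reproduces the headline numbers."""
        annual_m = {"promotion": 334.0, "topup": 233.0, "hwf": 174.0,
                    "soap": 497.0, "water": 127.0}
        streams = [
            CostStream("LDC", "rural", cat,
                       np.full(10, v * 1e6), np.full(10, v * 1e6))
            for cat, v in annual_m.items()
        ]
        formative = np.zeros(10)
        formative[0] = 5e6
        streams.append(CostStream("LDC", "national", "formative", formative, formative))
        summary = aggregate_total(streams, params)
        assert round(summary["total_usd2019"] / 1e9, 1) == 13.7
        assert round(summary["promotion_only_total_usd2019"] / 1e9, 1) == 5.7
        assert round(summary["facilities_supplies_total_usd2019"] / 1e9, 1) == 8.0
        assert summary["capital_share_pct"] == 37
        assert summary["category_shares_pct"] == {
            "formative": 0, "promotion": 24, "topup": 17,
            "hwf": 13, "soap": 36, "water": 9,
        }


class TestRoundTrip:
    def test_streams_csv_reaggregates_to_the_summary(self, small_inputs, tmp_path):
        streams = model_cost_streams(
            small_inputs.table, small_inputs.dists, small_inputs.factors,
            small_inputs.params, small_inputs.scenario,
        )
        summary = aggregate_total(streams, small_inputs.params)
        df = streams_frame(streams, small_inputs.params)
        path = tmp_path / "streams.csv"
        df.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        totals = back.groupby("category")["discounted_usd2019"].sum()
        for cat, expect in summary["category_totals_usd2019"].items():
            assert totals[cat] == pytest.approx(expect, rel=1e-9)
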