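"""Price standardisation, pooling, gamma matching and localisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hhcost import (
    CostParameters,
    PricePoint,
    annual_water_price,
    build_price_distributions,
    gamma_from_moments,
    localize_price,
    pool_prices,
    standardize_price,
)
from hhcost.prices import median_cv

from conftest import flat_factors, make_stratum


class TestStandardize:
    def test_no_inflation_step(self):
        ef = flat_factors(ppp=2.0)
        pp = PricePoint("soap_annual", 100.0, "AAA", 2019, "AAA")
        assert standardize_price(pp, ef) == pytest.approx(50.0)

    def test_deflator_then_ppp(self):
        from hhcost import EconomicFactors

        ef = EconomicFactors(
            country_code="AAA",
            deflator={2015: 80.0, 2019: 100.0},
            ppp_lcu_per_int_dollar=2.0,
            fx_lcu_per_usd={2015: 4.0, 2019: 4.0},
        )
        pp = PricePoint("soap_annual", 100.0, "AAA", 2015, "AAA")
        assert standardize_price(pp, ef) == pytest.approx(62.5)

    def test_usd_points_converted_through_local_currency(self):
        # a US$ price is moved to LCU at the price-year rate before deflation
        ef = flat_factors(ppp=2.0, fx=4.0)
        in_usd = PricePoint("soap_annual", 25.0, "USD", 2019, "AAA")
        in_lcu = PricePoint("soap_annual", 100.0, "AAA", 2019, "AAA")
        assert standardize_price(in_usd, ef) == pytest.approx(
            standardize_price(in_lcu, ef)
        )

    def test_country_mismatch_and_missing_year(self):
        ef = flat_factors()
        with pytest.raises(ValueError, match="factors are for"):
            standardize_price(PricePoint("hwf", 10.0, "BBB", 2019, "BBB"), ef)
        with pytest.raises(ValueError, match="deflator"):
            standardize_price(PricePoint("hwf", 10.0, "AAA", 1995, "AAA"), ef)

    def test_pooling_in_international_dollars_removes_price_level_bias(self):
        # the same I$42 basket localises to very different US$ amounts in a
        # low-price vs a higher-price economy
        low = flat_factors(code="AAA", ppp=10.0, fx=42.0)
        high = flat_factors(code="BBB", ppp=18.0, fx=42.0)
        from hhcost import PriceDistribution

        dist = PriceDistribution("soap_annual", 42.0, 6.0, *_shape_scale(42.0, 6.0), 10)
        assert localize_price(dist, low).usd_2019 == pytest.approx(10.0)
        assert localize_price(dist, high).usd_2019 == pytest.approx(18.0)


def _shape_scale(mean, se):
    return (mean / se) ** 2, se**2 / mean


class TestPooling:
    def test_textbook_mean_and_se(self):
        d = pool_prices([30.0, 40.0, 50.0], "hwf")
        assert d.i_mean == pytest.approx(40.0)
        assert d.i_se == pytest.approx(10.0 / np.sqrt(3))
        assert not d.se_is_fallback

    def test_single_point_uses_fallback_cv(self):
        d = pool_prices([25.0], "formative_research", fallback_cv=0.25)
        assert d.i_mean == pytest.approx(25.0)
        assert d.i_se == pytest.approx(6.25)
        assert d.se_is_fallback

    def test_identical_points_direct_user_to_se_floor(self):
        with pytest.raises(ValueError, match="floor"):
            pool_prices([20.0, 20.0, 20.0], "hwf")

    def test_order_invariance(self):
        a = pool_prices([10.0, 30.0, 20.0], "hwf")
        b = pool_prices([30.0, 20.0, 10.0], "hwf")
        assert (a.i_mean, a.i_se) == (b.i_mean, b.i_se)

    def test_median_cv_over_multi_point_categories(self):
        groups = {"a": [10.0, 20.0], "b": [100.0], "c": [5.0, 5.0, 8.0]}
        cv = median_cv(groups)
        cvs = [
            np.std([10, 20], ddof=1) / np.sqrt(2) / 15.0,
            np.std([5, 5, 8], ddof=1) / np.sqrt(3) / 6.0,
        ]
        assert cv == pytest.approx(np.median(cvs))

    def test_identical_points_in_different_currencies_pool_identically(self):
        # one basket expressed in two currencies -> identical I$ values
        ef = flat_factors(ppp=2.0, fx=4.0)
        vals = [
            standardize_price(PricePoint("hwf", 100.0, "AAA", 2019, "AAA"), ef),
            standardize_price(PricePoint("hwf", 25.0, "USD", 2019, "AAA"), ef),
            standardize_price(PricePoint("hwf", 80.0, "AAA", 2019, "AAA"), ef),
        ]
        assert vals[0] == pytest.approx(vals[1])
        d = pool_prices(vals, "hwf")
        assert d.i_mean == pytest.approx(np.mean(vals))


class TestGammaMatching:
    @pytest.mark.parametrize("mean,se,shape,scale", [(4.0, 2.0, 4.0, 1.0), (10.0, 1.0, 100.0, 0.1)])
    def test_moment_matching(self, mean, se, shape, scale):
        assert gamma_from_moments(mean, se) == pytest.approx((shape, scale))

    @given(
        mean=st.floats(0.1, 1e4),
        cv=st.floats(0.01, 2.0),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_round_trip_identity(self, mean, cv):
        se = mean * cv
        shape, scale = gamma_from_moments(mean, se)
        assert shape * scale == pytest.approx(mean, rel=1e-10)
        assert np.sqrt(shape) * scale == pytest.approx(se, rel=1e-10)

    def test_invalid_moments(self):
        for mean, se in [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)]:
            with pytest.raises(ValueError):
                gamma_from_moments(mean, se)

    def test_draws_match_stated_moments(self):
        rng = np.random.default_rng(11)
        mean, se = 40.0, 6.0
        shape, scale = gamma_from_moments(mean, se)
        draws = rng.gamma(shape, scale, size=100_000)
        # CLT bound: sample mean within 4 standard errors of the mean
        assert abs(draws.mean() - mean) < 4 * draws.std() / np.sqrt(draws.size)


class TestLocalize:
    def test_parity_case(self):
        from hhcost import PriceDistribution

        dist = PriceDistribution("hwf", 42.0, 6.0, *_shape_scale(42.0, 6.0), 16)
        ef = flat_factors(ppp=3.0, fx=3.0)
        assert localize_price(dist, ef).usd_2019 == pytest.approx(42.0)

    def test_monotone_in_mean_and_ratio(self):
        from hhcost import PriceDistribution

        lo = PriceDistribution("hwf", 10.0, 2.0, *_shape_scale(10.0, 2.0), 5)
        hi = PriceDistribution("hwf", 20.0, 2.0, *_shape_scale(20.0, 2.0), 5)
        ef1 = flat_factors(ppp=1.0, fx=4.0)
        ef2 = flat_factors(ppp=2.0, fx=4.0)
        assert localize_price(hi, ef1).usd_2019 > localize_price(lo, ef1).usd_2019
        assert localize_price(lo, ef2).usd_2019 > localize_price(lo, ef1).usd_2019


class TestWaterPrice:
    def test_piped_only(self):
        cs = make_stratum(household_size=5.0, piped_share=1.0, piped_cost=1.0)
        p = annual_water_price(cs, CostParameters())
        assert p == pytest.approx(2.7375, abs=5e-3)

    def test_nonpiped_only(self):
        cs = make_stratum(household_size=5.0, piped_share=0.0, nonpiped_cost=2.0)
        assert annual_water_price(cs, CostParameters()) == pytest.approx(5.475)

    def test_zero_volume(self):
        cs = make_stratum()
        assert annual_water_price(cs, CostParameters(water_lpd=0.0)) == 0.0


class TestPipelineCalibration:
    def test_localised_medians_land_on_the_anchors(self, reference_inputs):
        """Full standardise-pool-localise pipeline hits the per-household
        US$ anchor medians within 15 %."""
        from hhcost.pipeline import per_household_medians
        from hhcost.synthetic import DEFAULT_ANCHORS

        med = per_household_medians(reference_inputs)
        ratios = np.array(
            [reference_inputs.factors[c].ppp_over_fx
             for c in reference_inputs.table.countries]
        )
        checks = {
            "promotion_base": med["promotion"],
            "hwf": med["hwf"],
            "soap_annual": med["soap_annual"],
            "promotion_alternative": float(
                np.median(reference_inputs.dists["promotion_alternative"].i_mean * ratios)
            ),
            "hwf_homemade": float(
                np.median(reference_inputs.dists["hwf_homemade"].i_mean * ratios)
            ),
        }
        for cat, value in checks.items():
            assert value == pytest.approx(DEFAULT_ANCHORS[cat], rel=0.15), cat
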