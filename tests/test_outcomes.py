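"""Outcome valuation: discounting, costs, DALYs, productivity, scaling."""

import dataclasses as dc
import math

import numpy as np
import pytest

import fopfl_caries as fc
from fopfl_caries.outcomes import (dalys_averted, discount_factor, incremental,
                                   productivity_loss_avoided, scale_to_population,
                                   treatment_costs)


@pytest.mark.parametrize("year,rate,expected", [
    (1, 0.03, 1.0),
    (2, 0.03, 1 / 1.03),
    (7, 0.0, 1.0),
])
def test_discount_factor(year, rate, expected):
    assert math.isclose(discount_factor(year, rate), expected)


def test_discount_factor_rejects_year_zero():
    with pytest.raises(fc.ValidationError):
        discount_factor(0, 0.03)


@pytest.mark.parametrize("lesions,cost,rate,expected", [
    ([1], 74.10, 0.0, 74.10),
    ([0, 0, 0], 74.10, 0.03, 0.0),
    ([1, 1], 100.0, 0.03, 100.0 * (1 + 1 / 1.03)),
])
def test_treatment_costs(lesions, cost, rate, expected):
    assert math.isclose(treatment_costs(lesions, cost, rate), expected)


def test_dalys_averted_per_lesion_factor():
    params = fc.DalyParams()
    assert math.isclose(dalys_averted([1], params, 0.0), 677.62 / 2_370_715)
    # a zero disability weight annihilates any trajectory
    zero_weight = fc.DalyParams(p_symptomatic=0.3, duration=0.5, disability_weight=0.0)
    assert dalys_averted([10, 20, 30], zero_weight, 0.03) == 0.0


@pytest.mark.parametrize("dalys,gdp,expected", [
    (0.0, 40_332.0, 0.0),
    (1.0, 40_332.0, 40_332.0),
    (677.62, 40_332.0, 677.62 * 40_332.0),
])
def test_productivity_valuation(dalys, gdp, expected):
    assert math.isclose(productivity_loss_avoided(dalys, gdp), expected)


def test_productivity_round_trips_headline_ratio():
    gdp = 27.33e6 / 677.62
    assert productivity_loss_avoided(677.62, gdp) == pytest.approx(27.33e6)


@pytest.mark.parametrize("total,n,pop,expected", [
    (500, 1_000, 1_000, 500.0),
    (500, 1_000, 2_000_000, 1_000_000.0),
    (0, 50, 9_999, 0.0),
])
def test_scale_to_population(total, n, pop, expected):
    assert scale_to_population(total, n, pop) == expected


class TestIncremental:
    def make_pair(self, base_counts, int_counts, n=1_000):
        mk = lambda c: fc.ScenarioResult("male 15-18", np.array(c), n)
        return mk(base_counts), mk(int_counts)

    @pytest.fixture()
    def stratum(self):
        return fc.Stratum("male", "15-18", 90.0, 0.2, 10_000)

    def test_identical_scenarios_all_zero(self, stratum):
        base, intv = self.make_pair([5, 5, 5], [5, 5, 5])
        res = incremental(base, intv, stratum, fc.EconomicParams())
        assert res.lesions_prevented == 0
        assert res.costs_avoided == res.dalys_averted == res.productivity_avoided == 0

    def test_undiscounted_cost_identity_is_exact(self, stratum):
        base, intv = self.make_pair([40, 35, 30], [20, 18, 15])
        eco = fc.EconomicParams(discount_rate=0.03)
        res = incremental(base, intv, stratum, eco)
        assert res.costs_avoided_undiscounted == res.lesions_prevented * eco.unit_cost

    def test_headline_cost_examples(self, stratum):
        # lesions x 74.10 at zero rate reproduces the published totals
        assert round(2_370_715 * 74.10 / 1e6, 2) == 175.67
        assert round(89_638 * 74.10 / 1e6, 2) == 6.64

    def test_discounted_leq_undiscounted(self, stratum):
        base, intv = self.make_pair([40, 35, 30], [20, 18, 15])
        res = incremental(base, intv, stratum, fc.EconomicParams(discount_rate=0.03))
        assert res.costs_avoided < res.costs_avoided_undiscounted
        assert res.dalys_averted < res.dalys_averted_undiscounted
        assert res.productivity_avoided < res.productivity_avoided_undiscounted
        res0 = incremental(base, intv, stratum, fc.EconomicParams(discount_rate=0.0))
        assert res0.costs_avoided == pytest.approx(res0.costs_avoided_undiscounted)

    def test_horizon_mismatch_rejected(self, stratum):
        base, _ = self.make_pair([1, 2, 3], [0, 0, 0])
        _, intv = self.make_pair([1, 2], [0, 0])
        with pytest.raises(fc.ValidationError):
            incremental(base, intv, stratum, fc.EconomicParams())

    def test_population_scaling_linear(self, stratum):
        base, intv = self.make_pair([40, 35, 30], [20, 18, 15])
        eco = fc.EconomicParams()
        res_small = incremental(base, intv, stratum, eco)
        doubled = dc.replace(stratum, population=20_000)
        res_big = incremental(base, intv, doubled, eco)
        assert res_big.lesions_prevented == pytest.approx(2 * res_small.lesions_prevented)
        assert res_big.costs_avoided == pytest.approx(2 * res_small.costs_avoided)


def test_aggregate_is_exact_fieldwise_sum():
    stratum = fc.Stratum("male", "15-18", 90.0, 0.2, 10_000)
    mk = lambda c, n: fc.ScenarioResult("male 15-18", np.array(c), n)
    eco = fc.EconomicParams()
    parts = [incremental(mk([30, 20], 500), mk([10, 5], 500), stratum, eco)
             for _ in range(3)]
    total = fc.aggregate(parts)
    assert total.stratum_label == "total"
    assert total.lesions_prevented == sum(p.lesions_prevented for p in parts)
    assert total.costs_avoided == sum(p.costs_avoided for p in parts)
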