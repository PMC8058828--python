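"""DSA ordering, PSA parameter draws, quadrant bookkeeping."""

import dataclasses as dc
import math

import numpy as np
import pytest

import fopfl_caries as fc
from fopfl_caries.sensitivity import (PsaSpec, classify_quadrant, draw_psa_config,
                                      quadrant_fractions, run_dsa, run_psa,
                                      _truncated_normal)
from fopfl_caries.engine import make_rng


ZERO_SD = {"incidence": 0.0, "effect_fraction": 0.0,
           "sugar_caries_slope": 0.0, "unit_cost": 0.0}


class TestDsa:
    def test_zero_effect_gives_zero_outcomes(self, small_cfg):
        [(_, total)] = run_dsa(small_cfg, [0.0])
        assert total.lesions_prevented == 0
        assert total.costs_avoided == total.dalys_averted == 0

    def test_base_case_bracketed_by_bounds(self, small_cfg):
        table = dict(run_dsa(small_cfg, [0.044, 0.066, 0.088]))
        lo, mid, hi = (table[e].lesions_prevented for e in (0.044, 0.066, 0.088))
        assert lo < mid < hi
        assert table[0.044].costs_avoided < table[0.088].costs_avoided

    def test_outputs_ordered_as_given(self, small_cfg):
        out = run_dsa(small_cfg, [0.088, 0.044])
        assert [e for e, _ in out] == [0.088, 0.044]


class TestDraws:
    def test_zero_sd_returns_base_values(self, default_cfg):
        spec = PsaSpec(n_runs=1, n_individuals=100, sd_fractions=dict(ZERO_SD), seed=1)
        drawn = draw_psa_config(default_cfg, spec, run_id=0)
        assert drawn.economics.unit_cost == default_cfg.economics.unit_cost
        assert drawn.intervention.effect_fraction == default_cfg.intervention.effect_fraction
        assert [s.incidence for s in drawn.strata] == \
               [s.incidence for s in default_cfg.strata]

    def test_unit_cost_draws_centered_on_mean(self, default_cfg):
        """Sample mean of n=10,000 draws within 3 sd/sqrt(n) of EUR 74.10."""
        spec = PsaSpec(n_runs=10_000, n_individuals=100, seed=3)
        draws = np.array([draw_psa_config(default_cfg, spec, r).economics.unit_cost
                          for r in range(10_000)])
        sd = 0.20 * 74.10
        assert abs(draws.mean() - 74.10) < 3 * sd / math.sqrt(10_000)
        assert abs(draws.std() - sd) / sd < 0.05

    def test_draws_reproducible_per_run_id(self, default_cfg):
        spec = PsaSpec(n_runs=5, n_individuals=100, seed=9)
        a = draw_psa_config(default_cfg, spec, 3)
        b = draw_psa_config(default_cfg, spec, 3)
        assert a == b
        assert a != draw_psa_config(default_cfg, spec, 4)

    def test_truncation_never_leaves_domain(self):
        rng = make_rng(0, 1)
        draws = [_truncated_normal(rng, 0.5, 5.0, 0.0, 1.0) for _ in range(500)]
        assert all(0.0 <= d <= 1.0 for d in draws)
        # forced out-of-domain: mean far below bound still yields legal values
        assert _truncated_normal(make_rng(0, 2), -10.0, 0.1, 0.0, 1.0) >= 0.0

    def test_incidence_draws_stay_probabilities(self, default_cfg):
        spec = PsaSpec(n_runs=200, n_individuals=100, seed=5,
                       sd_fractions={"incidence": 0.9})
        for r in range(200):
            drawn = draw_psa_config(default_cfg, spec, r)
            assert all(0.0 <= s.incidence <= 1.0 for s in drawn.strata)


class TestQuadrants:
    @pytest.mark.parametrize("effect,cost,expected", [
        (10.0, -5.0, "SE"),
        (10.0, 5.0, "NE"),
        (-10.0, 5.0, "NW"),
        (-10.0, -5.0, "SW"),
        (10.0, 0.0, "SE"),  # zero cost counts as the cost-saving side
        (0.0, -5.0, "SE"),  # zero effect counts as the effective side
    ])
    def test_classification(self, effect, cost, expected):
        assert classify_quadrant(effect, cost) == expected

    def test_fractions_sum_to_one(self):
        pts = [fc.PsaPoint(i, e, c, classify_quadrant(e, c))
               for i, (e, c) in enumerate([(1, -1), (1, 1), (-1, 1), (1, -2)])]
        fr = quadrant_fractions(pts)
        assert sum(fr.values()) == 1.0
        assert fr == {"SE": 0.5, "NE": 0.25, "NW": 0.25, "SW": 0.0}

    def test_two_opposite_points(self):
        pts = [fc.PsaPoint(0, 1.0, -1.0, "SE"), fc.PsaPoint(1, -1.0, 1.0, "NW")]
        fr = quadrant_fractions(pts)
        assert fr["SE"] == fr["NW"] == 0.5

    def test_empty_rejected(self):
        with pytest.raises(fc.ValidationError):
            quadrant_fractions([])


class TestRunPsa:
    def test_zero_uncertainty_repeats_base_case(self, default_cfg):
        spec = PsaSpec(n_runs=4, n_individuals=2_000,
                       sd_fractions=dict(ZERO_SD), seed=11)
        points = run_psa(default_cfg, spec)
        assert len({(p.incremental_effect, p.incremental_cost) for p in points}) == 1
        assert all(p.quadrant == "SE" for p in points)

    def test_zero_effect_zero_sd_gives_zero_increment(self, default_cfg):
        cfg = default_cfg.with_effect(0.0)
        spec = PsaSpec(n_runs=3, n_individuals=2_000,
                       sd_fractions=dict(ZERO_SD), seed=11)
        for p in run_psa(cfg, spec):
            assert p.incremental_effect == 0.0
            assert p.incremental_cost == 0.0

    def test_small_psa_all_points_bottom_right(self, default_cfg):
        spec = PsaSpec(n_runs=25, n_individuals=5_000, seed=13)
        points = run_psa(default_cfg, spec)
        assert quadrant_fractions(points)["SE"] == 1.0
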