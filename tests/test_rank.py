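"""Glicko ratings, change-point detection, dominance metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from vbsphenotyper.changepoint import CpdParams, detect_change_points, normalized_change_points
from vbsphenotyper.glicko import (
    GlickoParams,
    expected_score,
    final_ratings,
    glicko_trajectories,
    glicko_update,
)
from vbsphenotyper.hierarchy import blanchard_score, hierarchy_metrics
from vbsphenotyper.sim import simulate_despotic_outcomes


def oracle_glicko_step(r, rd, r_opp, rd_opp, score):
    """Independent single-step implementation of Glickman's published
    update equations, coded directly from the formulas."""
    q = math.log(10.0) / 400.0
    g = 1.0 / math.sqrt(1.0 + 3.0 * (q**2) * (rd_opp**2) / (math.pi**2))
    e = 1.0 / (1.0 + 10.0 ** (-g * (r - r_opp) / 400.0))
    d2 = 1.0 / ((q**2) * (g**2) * e * (1.0 - e))
    r_new = r + q / (1.0 / rd**2 + 1.0 / d2) * g * (score - e)
    rd_new = math.sqrt((1.0 / rd**2 + 1.0 / d2) ** -1)
    return r_new, rd_new


class TestGlicko:
    def test_single_step_matches_independent_oracle(self):
        for r, rd, ro, rdo, s in [
            (1500.0, 350.0, 1500.0, 350.0, 1.0),
            (1500.0, 350.0, 1500.0, 350.0, 0.0),
            (2200.0, 300.0, 2350.0, 120.0, 1.0),
            (2000.0, 80.0, 2400.0, 250.0, 0.0),
        ]:
            got = glicko_update(r, rd, ro, rdo, s)
            want = oracle_glicko_step(r, rd, ro, rdo, s)
            assert got[0] == pytest.approx(want[0], abs=1e-9)
            assert got[1] == pytest.approx(want[1], abs=1e-9)

    def test_equal_opponents_symmetric_update(self):
        rw, _ = glicko_update(2200.0, 300.0, 2200.0, 300.0, 1.0)
        rl, _ = glicko_update(2200.0, 300.0, 2200.0, 300.0, 0.0)
        assert rw > 2200.0 > rl
        assert rw - 2200.0 == pytest.approx(2200.0 - rl)

    def test_expected_score_half_at_equal_ratings(self):
        for rd in (30.0, 300.0, 350.0):
            assert expected_score(1700.0, 1700.0, rd) == pytest.approx(0.5)

    def test_expected_score_monotone_in_rating_difference(self):
        es = [expected_score(2200.0 + d, 2200.0, 300.0) for d in range(-400, 401, 100)]
        assert all(b > a for a, b in zip(es, es[1:]))

    def test_update_magnitude_shrinks_with_certainty(self):
        big, _ = glicko_update(2200.0, 300.0, 2200.0, 300.0, 1.0)
        small, _ = glicko_update(2200.0, 60.0, 2200.0, 300.0, 1.0)
        assert big - 2200.0 > small - 2200.0

    def test_trajectory_bookkeeping(self):
        animals = ["a", "b", "c"]
        ratings, deviations = glicko_trajectories(
            [("a", "b"), ("a", "c"), ("b", "c")], animals
        )
        assert len(ratings) == 4
        assert (ratings.iloc[0] == 2200.0).all()
        assert (deviations.iloc[0] == 300.0).all()
        # winner of game 1 rises, loser falls, bystander untouched
        assert ratings.loc[1, "a"] > 2200.0 > ratings.loc[1, "b"]
        assert ratings.loc[1, "c"] == 2200.0
        # replay is exact
        again, _ = glicko_trajectories([("a", "b"), ("a", "c"), ("b", "c")], animals)
        pd.testing.assert_frame_equal(ratings, again)

    def test_empty_outcomes_stay_initial(self):
        ratings, _ = glicko_trajectories([], ["a", "b"])
        assert (ratings.iloc[-1] == 2200.0).all()

    def test_self_play_rejected(self):
        with pytest.raises(ValueError):
            glicko_trajectories([("a", "a")], ["a", "b"])


class TestChangePoints:
    def test_constant_has_none(self):
        assert detect_change_points(np.full(80, 2200.0)) == []

    def test_step_found_near_true_index(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(1500, 1, 50), rng.normal(1700, 1, 50)])
        cps = detect_change_points(x)
        assert len(cps) == 1
        assert abs(cps[0] - 50) <= 3

    def test_step_matches_offline_least_squares_break(self):
        """Single-break least-squares oracle: the split minimizing the
        summed within-segment variance agrees with the detector."""
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(1500, 1, 50), rng.normal(1700, 1, 50)])
        costs = [
            ((x[:k] - x[:k].mean()) ** 2).sum() + ((x[k:] - x[k:].mean()) ** 2).sum()
            for k in range(2, len(x) - 2)
        ]
        oracle = int(np.argmin(costs)) + 2
        cps = detect_change_points(x)
        assert abs(cps[0] - oracle) <= 3

    def test_additive_shift_invariance(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(0, 1, 60), rng.normal(25, 1, 60)])
        assert detect_change_points(x) == detect_change_points(x + 1.0e6)

    def test_invalid_hazard_rejected(self):
        with pytest.raises(ValueError):
            detect_change_points(np.arange(10.0), CpdParams(hazard=1.5))

    def test_normalized_count(self):
        assert normalized_change_points(3, 200) == pytest.approx(0.015)


class TestHierarchyMetrics:
    def test_documented_contrast_example(self):
        finals = pd.Series(
            {"a": 2500.0, "b": 2250.0, "c": 2200.0, "d": 2150.0,
             "e": 2100.0, "f": 2000.0}
        )
        m = hierarchy_metrics(finals)
        assert m.max_rating_contrast == pytest.approx(500.0)
        # threshold = 2200 + 500/3 = 2366.7 -> only the top animal
        assert m.dominants == ("a",)

    def test_all_equal_no_dominants(self):
        finals = pd.Series({c: 2200.0 for c in "abcdef"})
        m = hierarchy_metrics(finals)
        assert m.max_rating_contrast == 0.0
        assert m.dominants == ()

    def test_two_animals_can_be_dominant(self):
        finals = pd.Series(
            {"a": 2500.0, "b": 2450.0, "c": 2150.0, "d": 2100.0,
             "e": 2050.0, "f": 2000.0}
        )
        m = hierarchy_metrics(finals)
        assert set(m.dominants) == {"a", "b"}

    def test_minimum_baseline_variant(self):
        finals = pd.Series(
            {"a": 2350.0, "b": 2210.0, "c": 2200.0, "d": 2190.0,
             "e": 2180.0, "f": 2050.0}
        )
        default = hierarchy_metrics(finals, baseline="initial")
        alt = hierarchy_metrics(finals, baseline="minimum")
        # contrast 300: threshold 2300 from the initial rating,
        # 2150 from the group minimum
        assert default.dominants == ("a",)
        assert set(alt.dominants) == {"a", "b", "c", "d", "e"}

    def test_despotic_groups_have_one_dominant(self):
        """A clear despot (high win rate) is flagged as the unique
        dominant in nearly all simulated groups."""
        animals = [f"a{i + 1}" for i in range(6)]
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            outcomes = simulate_despotic_outcomes(150, 6, 0.7, rng)
            ratings, _ = glicko_trajectories(outcomes, animals)
            m = hierarchy_metrics(final_ratings(ratings))
            ok += len(m.dominants) == 1
        assert ok >= 95


class TestBlanchard:
    def test_top_on_both_measures(self):
        oa = pd.Series([60, 50, 40, 30, 20, 10], index=list("abcdef"))
        wl = pd.Series([1, 2, 3, 4, 5, 6], index=list("abcdef"))
        b = blanchard_score(oa, wl)
        assert b["a"] == 6.0
        assert b["f"] == 1.0

    def test_mixed_ranks_average(self):
        oa = pd.Series([60, 50, 40, 30, 20, 10], index=list("abcdef"))
        wl = pd.Series([2, 1, 3, 4, 6, 5], index=list("abcdef"))
        b = blanchard_score(oa, wl)
        # animal a: rank 6 on open area, rank 5 on (low) weight loss
        assert b["a"] == pytest.approx(5.5)

    def test_tie_gets_mean_rank(self):
        oa = pd.Series([10, 20, 30, 40, 50, 50], index=list("abcdef"))
        wl = pd.Series([6, 5, 4, 3, 2, 1], index=list("abcdef"))
        b = blanchard_score(oa, wl)
        # e and f tie for open-area positions 5-6 -> 5.5 each on that rank
        assert b["e"] == pytest.approx((5.5 + 5) / 2)
        assert b["f"] == pytest.approx((5.5 + 6) / 2)

    def test_rank_sum_conservation(self, rng):
        for _ in range(20):
            oa = pd.Series(rng.normal(size=6), index=list("abcdef"))
            wl = pd.Series(rng.normal(size=6), index=list("abcdef"))
            assert blanchard_score(oa, wl).mean() == pytest.approx(3.5)
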