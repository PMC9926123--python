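"""Operant and classical test scoring."""

import numpy as np
import pandas as pd
import pytest

from vbsphenotyper.tasks import (
    DiscountingCurve,
    InsufficientDataError,
    classify_decision_maker,
    discounting_auc,
    dlbox_risk_index,
    fiext_profile,
    flexibility_score,
    odds,
    odor_preference,
    physiology_changes,
    rgt_profile,
    srt_scores,
)


def _rgt_log(times, adv, sides=None, latencies=None):
    n = len(times)
    return pd.DataFrame(
        {
            "animal": ["a"] * n,
            "time_s": times,
            "side": sides if sides is not None else
            ["left" if x else "right" for x in adv],
            "advantageous": adv,
            "latency_s": latencies if latencies is not None else [1.0] * n,
        }
    )


class TestRgt:
    @pytest.mark.parametrize(
        "pct,cls", [(80.0, "GDM"), (50.0, "INT"), (20.0, "PDM"),
                    (70.0, "INT"), (30.0, "INT"), (100.0, "GDM")]
    )
    def test_class_thresholds_strict(self, pct, cls):
        assert classify_decision_maker(pct) == cls

    def test_last20_and_boundary(self):
        # 10 trials in the last 20 min, 7 advantageous -> 70% -> INT
        times = [2500.0 + 100 * i for i in range(10)]
        adv = [True] * 7 + [False] * 3
        prof = rgt_profile(_rgt_log(times, adv))
        assert prof.last20_pct == pytest.approx(70.0)
        assert prof.dm_class == "INT"

    def test_all_advantageous_is_gdm(self):
        times = list(np.linspace(10, 3590, 36))
        prof = rgt_profile(_rgt_log(times, [True] * 36))
        assert prof.last20_pct == 100.0
        assert prof.dm_class == "GDM"
        assert all(b == 100.0 for b in prof.advantageous_pct_per_10min)

    def test_empty_or_truncated_session_raises(self):
        with pytest.raises(InsufficientDataError):
            rgt_profile(_rgt_log([], []))
        with pytest.raises(InsufficientDataError):
            rgt_profile(_rgt_log([100.0, 200.0], [True, False]))

    def test_retimestamping_preserves_class(self):
        times = [2450.0 + 100 * i for i in range(11)]
        adv = [True] * 9 + [False] * 2
        a = rgt_profile(_rgt_log(times, adv))
        squeezed = [2400.0 + 90 * i for i in range(11)]
        b = rgt_profile(_rgt_log(squeezed, adv))
        assert a.dm_class == b.dm_class


class TestFlexibility:
    def _logs(self, rev_frac_other):
        rgt = _rgt_log([float(i) for i in range(10)], [True] * 10)  # prefers left
        n = 20
        k = int(round(rev_frac_other * n))
        rev = pd.DataFrame(
            {
                "animal": ["a"] * n,
                "time_s": [2400.0 + 60 * i for i in range(n)],
                "side": ["right"] * k + ["left"] * (n - k),
            }
        )
        return rgt, rev

    @pytest.mark.parametrize(
        "frac,cls", [(1.0, "flexible"), (0.5, "undecided"), (0.35, "inflexible"),
                     (0.6, "undecided"), (0.4, "undecided")]
    )
    def test_classes(self, frac, cls):
        score, got = flexibility_score(*self._logs(frac))
        assert got == cls
        assert score == pytest.approx(100 * frac)


class TestDiscounting:
    def test_odds_transform(self):
        assert odds(1.0) == 0.0
        assert odds(0.2) == pytest.approx(4.0)
        assert odds(0.09) == pytest.approx(10.11, abs=0.005)
        with pytest.raises(ValueError):
            odds(0.0)

    def test_flat_curve_auc_one(self):
        c = DiscountingCurve(
            np.array([0.0, 10.0, 20.0, 30.0, 40.0]), np.full(5, 82.0), 82.0, "delay"
        )
        assert discounting_auc(c) == pytest.approx(1.0)

    def test_two_point_toy(self):
        c = DiscountingCurve(np.array([0.0, 40.0]), np.array([90.0, 0.0]), 90.0, "delay")
        assert discounting_auc(c) == pytest.approx(0.5)

    def test_probability_curve_anchored_at_training(self):
        # preference falls linearly in odds space from the training level
        probs = np.array([0.66, 0.33, 0.20, 0.14, 0.09])
        x = np.array([odds(p) for p in probs]) / odds(0.09)
        prefs = 80.0 * (1 - x)
        c = DiscountingCurve(probs, prefs, 80.0, "probability")
        assert discounting_auc(c) == pytest.approx(0.5, abs=1e-9)

    def test_missing_level_reported(self):
        c = DiscountingCurve(np.array([0.0, 10.0]), np.array([80.0, 60.0]), 80.0, "delay")
        with pytest.raises(InsufficientDataError, match="30"):
            discounting_auc(c, expected_levels=(0.0, 10.0, 20.0, 30.0, 40.0))

    def test_dominated_curve_has_smaller_auc(self, rng):
        levels = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        hi = np.clip(rng.uniform(40, 90, 5), 0, None)
        lo = hi - rng.uniform(0, 20, 5)
        a_hi = discounting_auc(DiscountingCurve(levels, hi, 90.0, "delay"))
        a_lo = discounting_auc(DiscountingCurve(levels, np.clip(lo, 0, None), 90.0, "delay"))
        assert a_hi >= a_lo


class TestFiext:
    def _log(self, pokes_per_fi=3, pokes_per_ext=4):
        rows = []
        for block in (1, 2):
            for fi in range(1, 8):
                for k in range(pokes_per_fi):
                    rows.append(("a", block, "FI", fi, 5.0 + 10.0 * k))
            for k in range(pokes_per_ext):
                rows.append(("a", block, "EXT", 1, 30.0 + 60.0 * k))
        return pd.DataFrame(
            rows, columns=["animal", "block", "period_type", "period_index",
                           "poke_time_s"])

    def test_two_exclusions_leave_twelve(self):
        prof = fiext_profile(self._log())
        assert prof["n_analyzed_fi"] == 12
        assert len(prof["fi_totals"]) == 12
        assert (1, 1) not in prof["fi_totals"] and (2, 1) not in prof["fi_totals"]

    def test_binning(self):
        prof = fiext_profile(self._log())
        assert len(prof["fi_bins_10s"]) == 6
        assert len(prof["ext_bins_1min"]) == 5
        # pokes at 30, 90, 150, 210 s per EXT, both blocks
        assert prof["ext_bins_1min"].tolist() == [2, 2, 2, 2, 0]

    def test_zero_pokes(self):
        prof = fiext_profile(self._log(0, 0))
        assert prof["fi_mean"] == 0.0
        assert prof["ext_bins_1min"].sum() == 0


class TestClassical:
    def test_srt_ratios(self):
        scores = srt_scores({"Hab": 30.0, "E1": 30.0, "E3": 10.0,
                             "E4": 10.0, "Enew": 40.0})
        assert scores["social_preference"] == pytest.approx(1.0)
        assert scores["short_term_recognition"] == pytest.approx(3.0)
        assert scores["long_term_recognition"] == pytest.approx(0.25)

    def test_srt_zero_denominator_flagged(self):
        scores = srt_scores({"Hab": 0.0, "E1": 30.0, "E3": 10.0,
                             "E4": 10.0, "Enew": 40.0})
        assert np.isnan(scores["social_preference"])

    def test_odor_fraction(self):
        assert odor_preference(30.0, 10.0) == pytest.approx(0.75)
        assert np.isnan(odor_preference(0.0, 0.0))

    def test_dlbox_index(self):
        visits = pd.DataFrame(
            {"first_dark_visit_s": [100.0, 50.0], "n_risk_assessments": [10, 5],
             "dark_time_s": [190.0, 45.0]},
            index=["a", "b"],
        )
        idx = dlbox_risk_index(visits)
        assert idx["a"] == 0.0
        assert idx["b"] == pytest.approx(200.0)

    def test_dlbox_never_dark_gets_cohort_max(self):
        visits = pd.DataFrame(
            {"first_dark_visit_s": [80.0, 0.0], "n_risk_assessments": [20, 0],
             "dark_time_s": [200.0, 0.0]},
            index=["a", "b"],
        )
        idx = dlbox_risk_index(visits)
        assert idx["b"] == pytest.approx(300.0)


class TestPhysiology:
    def test_no_change(self):
        out = physiology_changes(pd.Series([250.0]), pd.Series([250.0]))
        assert out["loss"].iloc[0] == 0.0
        assert out["pct_change"].iloc[0] == 0.0

    def test_weight_loss(self):
        out = physiology_changes(pd.Series([250.0]), pd.Series([240.0]))
        assert out["loss"].iloc[0] == pytest.approx(10.0)
        assert out["pct_change"].iloc[0] == pytest.approx(-4.0)

    def test_corticosterone_rise(self):
        out = physiology_changes(pd.Series([2.0]), pd.Series([6.0]))
        assert out["pct_change"].iloc[0] == pytest.approx(200.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            physiology_changes(pd.Series([0.0]), pd.Series([1.0]))
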