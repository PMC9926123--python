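"""The synthetic-colony generator: determinism, configured rates,
latent-type recovery, validation."""

import numpy as np
import pandas as pd
import pytest

from vbsphenotyper.sim import (
    DDT_DELAYS_S,
    SimConfig,
    simulate_colony,
    simulate_discounting,
    simulate_rgt_cohort,
    wildtype_params,
)
from vbsphenotyper.sim.config import GenotypeParams
from vbsphenotyper.tasks import InsufficientDataError, rgt_profile, score_discounting_log, discounting_auc
from dataclasses import replace


SMALL = {"wildtype": 1, "knockout": 1}


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = SimConfig(n_groups_per_genotype=SMALL)
        a = simulate_colony(cfg, seed=5)
        b = simulate_colony(cfg, seed=5)
        pd.testing.assert_frame_equal(a.detections, b.detections)
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.physiology, b.physiology)
        for k in a.task_logs:
            pd.testing.assert_frame_equal(a.task_logs[k], b.task_logs[k])

    def test_different_seeds_differ(self):
        cfg = SimConfig(n_groups_per_genotype=SMALL)
        a = simulate_colony(cfg, seed=5)
        b = simulate_colony(cfg, seed=6)
        assert not a.events.equals(b.events)


class TestConfigValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            replace(wildtype_params(), event_rates={"huddling": -1.0})

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            replace(wildtype_params(), dm_mixture=(0.5, 0.2, 0.2))

    def test_group_size_minimum(self):
        with pytest.raises(ValueError, match="group_size"):
            SimConfig(group_size=1)

    def test_grid_without_adjacency_rejected(self):
        from vbsphenotyper.grid import ZoneGrid

        with pytest.raises(ValueError, match="no adjacent"):
            ZoneGrid(
                np.array([[0.0, 0.0], [1.0, 0.0]]),
                ("open_area", "burrow"), {0: (1,), 1: ()},
            )


class TestEventRates:
    def test_poisson_mean_within_three_se(self):
        """lambda = 10 events/animal/phase over 8 scored phases: observed
        per-animal mean within 3 SE of 80 (Poisson oracle)."""
        lam, phases = 10.0, 8
        params = replace(
            wildtype_params(),
            event_rates={"huddling": lam},
            light_phase_event_factor=1.0,
        )
        cfg = SimConfig(
            n_groups_per_genotype={"wildtype": 4},
            genotype_params={"wildtype": params},
        )
        study = simulate_colony(cfg, seed=2)
        n_animals = len(study.animals)
        counts = study.events.groupby("actor").size()
        counts = counts.reindex(study.animals["animal"], fill_value=0)
        se = np.sqrt(lam * phases / n_animals)
        assert abs(counts.mean() - lam * phases) < 3 * se

    def test_chi2_goodness_of_fit_across_seeds(self):
        """Total event counts per seed follow the configured Poisson law
        (chi-squared test on the normal approximation, alpha = 0.01)."""
        from scipy import stats as sps

        lam = 6.0
        params = replace(
            wildtype_params(), event_rates={"sniffing": lam},
            light_phase_event_factor=1.0,
        )
        cfg = SimConfig(
            n_groups_per_genotype={"wildtype": 1},
            genotype_params={"wildtype": params},
        )
        totals = []
        for seed in range(60):
            study = simulate_colony(cfg, seed=seed)
            totals.append(len(study.events))
        mu = lam * 8 * 6  # 8 phases x 6 animals
        z = (np.array(totals) - mu) / np.sqrt(mu)
        stat = (z**2).sum()
        p = sps.chi2.sf(stat, df=len(totals))
        assert p > 0.01


class TestRgtGenerator:
    def test_latent_gdm_classified_gdm(self):
        cfg = SimConfig(n_groups_per_genotype=SMALL)
        params = cfg.genotype_params["wildtype"]
        assert params.dm_asymptote["GDM"] > 0.9
        rng = np.random.default_rng(0)
        log, latent = simulate_rgt_cohort(cfg, "wildtype", ["x"], rng)
        prof = rgt_profile(log[log["animal"] == "x"])
        if latent["x"] == "GDM":
            assert prof.dm_class == "GDM"

    def test_class_proportions_recovered(self):
        """47 simulated animals with mixture 0.74/0.09/0.17: every
        recovered class proportion inside its binomial 95% interval."""
        cfg = SimConfig()
        rng = np.random.default_rng(12)
        animals = [f"x{i}" for i in range(47)]
        log, latent = simulate_rgt_cohort(cfg, "wildtype", animals, rng)
        classes = pd.Series(
            {a: rgt_profile(log[log["animal"] == a]).dm_class for a in animals}
        )
        for cls, p0 in (("GDM", 0.74), ("INT", 0.09), ("PDM", 0.17)):
            frac = (classes == cls).mean()
            half = 1.96 * np.sqrt(p0 * (1 - p0) / 47)
            assert abs(frac - p0) <= half + 1e-9

    def test_zero_length_session(self):
        cfg = SimConfig(n_groups_per_genotype=SMALL)
        rng = np.random.default_rng(0)
        log, _ = simulate_rgt_cohort(cfg, "wildtype", [], rng)
        assert len(log) == 0
        with pytest.raises(InsufficientDataError):
            rgt_profile(log)


class TestDiscountingGenerator:
    def _auc(self, k, seed=0, temperature=0.8):
        params = replace(
            wildtype_params(), ddt_k_per_s=k, choice_temperature=temperature
        )
        cfg = SimConfig(
            n_groups_per_genotype={"wildtype": 1},
            genotype_params={"wildtype": params},
        )
        rng = np.random.default_rng(seed)
        log = simulate_discounting(cfg, "wildtype", ["x"], "delay", rng)
        curve = score_discounting_log(log, "delay")["x"]
        return curve, discounting_auc(curve)

    def test_negligible_discounting_auc_near_one(self):
        curve, auc = self._auc(1e-6)
        assert auc > 0.95
        assert curve.preference_pct.min() > 90.0

    def test_extreme_discounting_auc_near_zero(self):
        # the k -> infinity limit needs low choice noise to show through
        curve, auc = self._auc(50.0, temperature=0.2)
        # switched to the small reward at the shortest nonzero delay
        assert curve.preference_pct[curve.levels == 10.0][0] < 10.0
        assert auc < 0.15

    def test_group_indifference_near_twenty_seconds(self):
        """With the default steepness the cohort's preference curve
        crosses 50% between the 10 s and 30 s delays."""
        cfg = SimConfig(n_groups_per_genotype={"wildtype": 2})
        rng = np.random.default_rng(4)
        animals = [f"x{i}" for i in range(12)]
        log = simulate_discounting(cfg, "wildtype", animals, "delay", rng)
        curves = score_discounting_log(log, "delay")
        mean_pref = np.mean(
            [c.preference_pct for c in curves.values()], axis=0
        )
        levels = next(iter(curves.values())).levels
        assert mean_pref[levels == 10.0][0] > 50.0
        assert mean_pref[levels == 30.0][0] < 50.0


class TestClassicalGenerator:
    def test_null_corticosterone_overlaps(self):
        """Identical corticosterone multipliers: the percent-variation
        rank-sum test is non-significant in >= 90% of seeds."""
        from vbsphenotyper.sim import null_config
        from vbsphenotyper.stats import rank_sum_W
        from vbsphenotyper.tasks import physiology_changes

        nonsig = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = null_config(seed=seed, n_groups=2)
            study = simulate_colony(cfg)
            phys = study.physiology.set_index("animal")
            pct = physiology_changes(
                phys["cort_before_ugg"], phys["cort_after_ugg"]
            )["pct_change"]
            geno = study.animals.set_index("animal")["genotype"]
            _, p = rank_sum_W(
                pct[geno == "wildtype"], pct[geno == "knockout"]
            )
            nonsig += p > 0.05
        assert nonsig >= 0.9 * n_seeds

    def test_separated_weight_change_near_complete_separation(self):
        """Means -2 g vs -10 g with sd 2: the rank-sum W approaches
        n_x * n_y (normal-overlap oracle: P(X > Y) ~= 0.998)."""
        from vbsphenotyper.stats import rank_sum_W
        from vbsphenotyper.tasks import physiology_changes

        wt = replace(wildtype_params(), weight_change_g=(-2.0, 2.0))
        ko = replace(wildtype_params(), name="knockout",
                     weight_change_g=(-10.0, 2.0))
        cfg = SimConfig(
            n_groups_per_genotype={"wildtype": 2, "knockout": 2},
            genotype_params={"wildtype": wt, "knockout": ko},
        )
        study = simulate_colony(cfg, seed=8)
        phys = study.physiology.set_index("animal")
        loss = physiology_changes(
            phys["weight_before_g"], phys["weight_after_g"]
        )["loss"]
        geno = study.animals.set_index("animal")["genotype"]
        w, p = rank_sum_W(loss[geno == "knockout"], loss[geno == "wildtype"])
        n_pairs = 12 * 12
        # expected W = n_pairs * P(loss_ko > loss_wt), a normal-overlap
        # probability with mean difference 8 g and sd sqrt(8)
        from scipy.stats import norm

        expect = n_pairs * norm.cdf(8 / np.sqrt(8))
        assert w >= 0.9 * expect
        assert p < 1e-4

    def test_negative_duration_rejected(self, toy_events):
        from vbsphenotyper.events import EventValidationError, validate_events

        bad = toy_events.copy()
        bad.loc[0, "duration_s"] = -1.0
        with pytest.raises(EventValidationError, match="negative duration"):
            validate_events(bad)
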