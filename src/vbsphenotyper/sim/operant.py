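"""Operant-task records: gambling task, its reversal, discounting, FIEXT.

Gambling task: each animal carries a latent decision-maker type (GDM /
INT / PDM, drawn from the configured mixture); its probability of an
advantageous choice ramps from indifference (0.5) to the type's
asymptote over the first 20 min and stays there, so the last-20-min
preference concentrates around the asymptote.  Penalty time-outs follow
the task contingencies (long 222/444 s on disadvantageous choices, short
6/12 s on advantageous ones, with probabilities 1/2 and 1/4).

Discounting: the large reward's value is discounted hyperbolically,
V = A / (1 + k D) over delay D or V = A / (1 + h * odds) over odds =
1/P - 1, and choices follow a logistic rule in (V_large - V_small) with
the configured temperature; two stable sessions are emitted per level,
already past the stability criterion (training/criterion logic is out of
scope).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    DDT_DELAYS_S,
    DM_CLASSES,
    FLEX_CLASSES,
    PDT_PROBABILITIES,
    SimConfig,
)

ADVANTAGEOUS_SIDE = "left"
LARGE_REWARD = 5.0
SMALL_REWARD = 1.0


def _draw_classes(rng, classes, mixture, n):
    return rng.choice(len(classes), size=n, p=np.asarray(mixture))


def _session_trial_times(rng, session_s=3600.0, mean_iti_s=25.0):
    times = np.cumsum(rng.exponential(mean_iti_s, int(session_s / mean_iti_s * 2)))
    return times[times < session_s]


def simulate_rgt_cohort(
    config: SimConfig, genotype: str, animals, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """60-min gambling-task trial logs; returns (log, latent classes)."""
    params = config.genotype_params[genotype]
    latent = _draw_classes(rng, DM_CLASSES, params.dm_mixture, len(animals))
    rows = []
    for animal, cls_idx in zip(animals, latent):
        cls = DM_CLASSES[cls_idx]
        asym = np.clip(
            params.dm_asymptote[cls] + rng.normal(0.0, 0.03), 0.02, 0.98
        )
        lat_mean = params.reward_latency_s[cls]
        times = _session_trial_times(rng)
        for t in times:
            p_adv = 0.5 + (asym - 0.5) * min(1.0, t / 1200.0)
            advantageous = bool(rng.random() < p_adv)
            side = ADVANTAGEOUS_SIDE if advantageous else "right"
            hole = (1 if advantageous else 3) + int(rng.integers(2))
            u = rng.random()
            if advantageous:
                penalty = 6.0 if u < 0.5 else (12.0 if u < 0.75 else 0.0)
                pellets = 1
            else:
                penalty = 222.0 if u < 0.5 else (444.0 if u < 0.75 else 0.0)
                pellets = 2
            rows.append(
                (
                    animal, float(t), hole, side, advantageous, pellets,
                    penalty, float(np.round(rng.lognormal(np.log(lat_mean), 0.4), 2)),
                )
            )
    log = pd.DataFrame(
        rows,
        columns=[
            "animal", "time_s", "hole", "side", "advantageous",
            "reward_pellets", "penalty_s", "latency_s",
        ],
    )
    return log, pd.Series(
        [DM_CLASSES[i] for i in latent], index=list(animals), name="dm_class"
    )


def simulate_reversed_rgt(
    config: SimConfig, genotype: str, animals, rgt_log: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """Reversal session: choices recorded by side, flexibility latent."""
    params = config.genotype_params[genotype]
    latent = _draw_classes(rng, FLEX_CLASSES, params.flex_mixture, len(animals))
    target = {"flexible": 0.85, "undecided": 0.5, "inflexible": 0.15}
    rows = []
    for animal, cls_idx in zip(animals, latent):
        cls = FLEX_CLASSES[cls_idx]
        goal = np.clip(target[cls] + rng.normal(0.0, 0.03), 0.02, 0.98)
        pref = rgt_log.loc[rgt_log["animal"] == animal, "side"]
        pref_side = pref.value_counts().idxmax() if len(pref) else ADVANTAGEOUS_SIDE
        other = "right" if pref_side == "left" else "left"
        for t in _session_trial_times(rng):
            p_other = 0.5 + (goal - 0.5) * min(1.0, t / 1200.0)
            side = other if rng.random() < p_other else pref_side
            rows.append((animal, float(t), side))
    log = pd.DataFrame(rows, columns=["animal", "time_s", "side"])
    return log, pd.Series(
        [FLEX_CLASSES[i] for i in latent], index=list(animals), name="flex_class"
    )


def _logistic_choice_prob(v_large, v_small, temperature):
    return 1.0 / (1.0 + np.exp(-(v_large - v_small) / temperature))


def simulate_discounting(
    config: SimConfig, genotype: str, animals, kind: str,
    rng: np.random.Generator, n_trials: int = 60,
) -> pd.DataFrame:
    """Stable-session discounting logs for one cohort.

    ``kind='delay'`` uses V = A / (1 + k D) over the standard delays;
    ``kind='probability'`` uses V = A / (1 + h * odds) over the standard
    probabilities.  Two already-stable sessions are emitted per level,
    plus two training sessions (delay 0 / certain reward).
    """
    params = config.genotype_params[genotype]
    if kind == "delay":
        levels = DDT_DELAYS_S
        steep_mean = params.ddt_k_per_s
    elif kind == "probability":
        levels = PDT_PROBABILITIES
        steep_mean = params.pdt_h_per_odds
    else:
        raise ValueError("kind must be 'delay' or 'probability'")
    rows = []
    for animal in animals:
        steep = steep_mean * float(np.exp(rng.normal(0.0, 0.25)))
        def v_large(level):
            if kind == "delay":
                return LARGE_REWARD / (1.0 + steep * level)
            return LARGE_REWARD / (1.0 + steep * (1.0 / level - 1.0))
        for session in (1, 2):
            p = _logistic_choice_prob(
                v_large(0.0 if kind == "delay" else 1.0),
                SMALL_REWARD, params.choice_temperature,
            )
            rows.append(
                (animal, "training", 0.0 if kind == "delay" else 1.0, session,
                 n_trials, int(rng.binomial(n_trials, p)))
            )
        for level in levels:
            p = _logistic_choice_prob(
                v_large(level), SMALL_REWARD, params.choice_temperature
            )
            for session in (1, 2):
                rows.append(
                    (animal, "test", float(level), session, n_trials,
                     int(rng.binomial(n_trials, p)))
                )
    return pd.DataFrame(
        rows,
        columns=["animal", "stage", "level", "session", "n_trials", "n_large"],
    )


def simulate_fiext(
    config: SimConfig, genotype: str, animals, rng: np.random.Generator
) -> pd.DataFrame:
    """Nose-poke logs of one FIEXT session per animal.

    Two blocks of seven 60-s fixed intervals plus one 5-min extinction;
    anticipatory pokes concentrate late in the FI, perseverative pokes
    decay over the EXT.
    """
    rows = []
    for animal in animals:
        fi_rate = np.clip(rng.normal(6.0, 2.0), 0.5, None)
        ext_rate = np.clip(rng.normal(12.0, 4.0), 1.0, None)
        for block in (1, 2):
            for fi in range(1, 8):
                for t in rng.beta(3.0, 1.0, rng.poisson(fi_rate)) * 60.0:
                    rows.append((animal, block, "FI", fi, float(np.round(t, 2))))
            for t in rng.beta(1.0, 2.5, rng.poisson(ext_rate)) * 300.0:
                rows.append((animal, block, "EXT", 1, float(np.round(t, 2))))
    return pd.DataFrame(
        rows,
        columns=["animal", "block", "period_type", "period_index", "poke_time_s"],
    )
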