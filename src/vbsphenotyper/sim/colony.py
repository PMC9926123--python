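"""Home-cage (VBS) part of the generator: movement, ethogram events,
physiology.

Movement model: each animal performs a discrete-time Markov walk over
the detector grid at 1-s resolution with self-transitions; it is
simulated through its embedded jump chain (the dwell at a detector is
geometric with the animal's mean dwell time, the jump goes to an
adjacent detector with probability proportional to the animal's
preference weight for that zone), which is statistically identical to
stepping the 1-Hz chain and far cheaper.  Genotype shapes the stationary
distribution (burrow-biased and short-dwelling for the depleted
genotype), which drives the roaming entropy, activity, place-preference
and open-area contrasts downstream.

Ethogram events: within each scored 4-h phase window the number of
events per grouped behavior category is Poisson with the configured
per-animal rate; initiators are drawn by actor propensity (the group's
despot is favored for aggressive and sexual behaviors), receivers
uniformly among cage mates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..ethogram import DYADIC_CATEGORIES, ETHOGRAM
from ..events import SCORED_PHASE_SECONDS
from .config import GenotypeParams, SimConfig

#: a concrete behavior emitted for each grouped label
_EMITTED_BEHAVIOR = {
    "huddling": ["huddle"],
    "sniffing": ["sniffing_anogenital", "sniffing_nose", "sniffing_body"],
    "allogrooming": ["allogrooming"],
    "attending": ["attending"],
    "general_aggression": ["attack", "fight", "pinning", "following"],
    "struggling_at_feeder": ["struggling_at_feeder"],
    "sexual": ["mounting", "embracing"],
    "defensive": ["flight", "freezing", "supine_posture"],
    "eating": ["eating"],
    "drinking": ["drinking"],
    "grooming": ["grooming"],
}


def _zone_weights(params: GenotypeParams, grid) -> np.ndarray:
    return np.array([params.zone_label_weights.get(lab, 1.0) for lab in grid.labels])


def _transition_cdf(grid, weights: np.ndarray) -> np.ndarray:
    """Per-zone cumulative jump distribution over the k zones."""
    k = grid.k
    cdf = np.zeros((k, k))
    for z in range(k):
        p = np.zeros(k)
        nbrs = list(grid.adjacency[z])
        w = weights[nbrs]
        if w.sum() <= 0:
            w = np.ones(len(nbrs))
        p[nbrs] = w / w.sum()
        cdf[z] = np.cumsum(p)
    return cdf


def simulate_movement(
    config: SimConfig, group_id: str, genotype: str, animals, rng: np.random.Generator
) -> pd.DataFrame:
    """Dwell-interval detection streams for one housed group."""
    params = config.genotype_params[genotype]
    grid = config.grid
    base_w = _zone_weights(params, grid)
    rows = []
    for animal in animals:
        # per-animal idiosyncrasy in preference and tempo
        w = base_w * np.exp(rng.normal(0.0, 0.2, grid.k))
        cdf = _transition_cdf(grid, w)
        dwell_mean = params.mean_dwell_s * float(np.exp(rng.normal(0.0, 0.15)))
        zone = int(rng.integers(grid.k))
        for day in range(1, config.n_days + 1):
            for phase in ("dark", "light"):
                mean_dwell = dwell_mean * (
                    params.light_phase_dwell_factor if phase == "light" else 1.0
                )
                t = 0.0
                horizon = float(config.phase_seconds)
                # geometric dwells == 1-Hz walk with self-loop prob 1 - 1/mean
                n_est = int(horizon / mean_dwell * 1.35) + 20
                dwells = rng.geometric(min(1.0, 1.0 / mean_dwell), n_est).astype(float)
                jumps = rng.random(n_est)
                for d, u in zip(dwells, jumps):
                    d = min(d, horizon - t)
                    rows.append((animal, group_id, day, phase, t, d, zone))
                    t += d
                    if t >= horizon:
                        break
                    zone = int(np.searchsorted(cdf[zone], u))
                else:  # exhausted the dwell budget before the horizon
                    if t < horizon:
                        rows.append(
                            (animal, group_id, day, phase, t, horizon - t, zone)
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "animal", "group_id", "day", "phase", "t_start_s", "duration_s",
            "detector",
        ],
    )


def simulate_events(
    config: SimConfig, group_id: str, genotype: str, animals, rng: np.random.Generator
) -> pd.DataFrame:
    """Scan-sampled ethogram events for one housed group."""
    params = config.genotype_params[genotype]
    animals = list(animals)
    n = len(animals)
    grid_k = config.grid.k
    rows = []
    for day in range(1, config.n_days + 1):
        for phase in ("dark", "light"):
            factor = params.light_phase_event_factor if phase == "light" else 1.0
            for grouped, rate in params.event_rates.items():
                lam = rate * factor * n
                count = rng.poisson(lam)
                if count == 0:
                    continue
                names = _EMITTED_BEHAVIOR[grouped]
                category = ETHOGRAM[names[0]].category
                dyadic = category in DYADIC_CATEGORIES
                despotic = category in ("aggressive", "sexual")
                actor_w = np.ones(n)
                if despotic:
                    actor_w[0] = params.despot_weight
                actor_p = actor_w / actor_w.sum()
                actor_idx = rng.choice(n, size=count, p=actor_p)
                times = np.sort(rng.uniform(0, SCORED_PHASE_SECONDS, count))
                for t, ai in zip(times, actor_idx):
                    receiver = None
                    if dyadic:
                        rj = int(rng.integers(n - 1))
                        receiver = animals[rj if rj < ai else rj + 1]
                    rows.append(
                        (
                            group_id, day, phase, float(t), animals[int(ai)],
                            receiver, names[int(rng.integers(len(names)))],
                            float(np.round(rng.gamma(2.0, 3.0), 1)),
                            int(rng.integers(grid_k)),
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "group_id", "day", "phase", "time_s", "actor", "receiver",
            "behavior", "duration_s", "zone",
        ],
    )


def simulate_physiology(
    config: SimConfig, genotype: str, animals, rng: np.random.Generator
) -> pd.DataFrame:
    """Pre/post body weight (g) and fecal corticosterone (ug/g)."""
    params = config.genotype_params[genotype]
    n = len(animals)
    before = rng.normal(*params.weight_before_g, n)
    change = rng.normal(*params.weight_change_g, n)
    cort_before = np.clip(rng.normal(*params.cort_before_ugg, n), 0.2, None)
    mult = np.clip(rng.normal(*params.cort_multiplier, n), 0.1, None)
    return pd.DataFrame(
        {
            "animal": list(animals),
            "weight_before_g": np.round(before, 1),
            "weight_after_g": np.round(before + change, 1),
            "cort_before_ugg": np.round(cort_before, 3),
            "cort_after_ugg": np.round(cort_before * mult, 3),
        }
    )
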