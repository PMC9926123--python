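"""Synthetic-colony generator.

``simulate_colony`` builds a full synthetic study — housed groups with
RFID detection streams, scan-sampled ethogram events, physiology, and
every operant/classical test record — with the statistical structure the
analysis pipeline assumes, so each downstream stage can be exercised and
validated without the original recordings.

Reproducibility: the master seed is expanded into one child RNG per
(component, group) through ``numpy.random.SeedSequence(master).spawn``
in a fixed documented order, so components are independent and the whole
study is byte-identical under the same config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classical import simulate_dlbox, simulate_odor, simulate_srt
from .colony import simulate_events, simulate_movement, simulate_physiology
from .config import (
    DDT_DELAYS_S,
    PDT_PROBABILITIES,
    GenotypeParams,
    SimConfig,
    config_from_yaml,
    knockout_params,
    null_config,
    wildtype_params,
)
from .operant import (
    simulate_discounting,
    simulate_fiext,
    simulate_reversed_rgt,
    simulate_rgt_cohort,
)

__all__ = [
    "SimConfig", "GenotypeParams", "SyntheticStudy", "simulate_colony",
    "simulate_despotic_outcomes", "wildtype_params", "knockout_params",
    "null_config", "config_from_yaml", "simulate_rgt_cohort",
    "simulate_discounting", "DDT_DELAYS_S", "PDT_PROBABILITIES",
]


@dataclass
class SyntheticStudy:
    """Everything a study produces, plus the generating truth."""

    animals: pd.DataFrame            # animal, group_id, genotype
    detections: pd.DataFrame
    events: pd.DataFrame
    physiology: pd.DataFrame
    task_logs: dict = field(default_factory=dict)
    latent: dict = field(default_factory=dict)
    truth: SimConfig | None = None

    @property
    def groups(self) -> pd.DataFrame:
        return self.animals.drop_duplicates("group_id")[["group_id", "genotype"]]

    def group_members(self, group_id: str) -> list:
        return self.animals.loc[
            self.animals["group_id"] == group_id, "animal"
        ].tolist()


def _roster(config: SimConfig) -> pd.DataFrame:
    rows = []
    for genotype in sorted(config.n_groups_per_genotype):
        for gi in range(config.n_groups_per_genotype[genotype]):
            group_id = f"{genotype}_g{gi + 1}"
            for ai in range(config.group_size):
                rows.append(
                    {
                        "animal": f"{group_id}_a{ai + 1}",
                        "group_id": group_id,
                        "genotype": genotype,
                    }
                )
    return pd.DataFrame(rows)


def simulate_colony(config: SimConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study from a config.

    ``seed`` overrides ``config.seed`` when given.  Same config + same
    seed gives byte-identical outputs.
    """
    config = config or SimConfig()
    master = config.seed if seed is None else seed
    roster = _roster(config)
    groups = roster.drop_duplicates("group_id")

    components = (
        "movement", "events", "physiology", "rgt", "reversed_rgt",
        "ddt", "pdt", "fiext", "srt", "odor", "dlbox",
    )
    seeds = dict(zip(components, np.random.SeedSequence(master).spawn(len(components))))
    rngs = {
        comp: {
            gid: np.random.default_rng(child)
            for gid, child in zip(
                groups["group_id"], seeds[comp].spawn(len(groups))
            )
        }
        for comp in components
    }

    detections, events, physiology = [], [], []
    logs = {k: [] for k in ("rgt", "reversed_rgt", "ddt", "pdt", "fiext")}
    classical = {k: [] for k in ("srt", "odor", "dlbox")}
    latent = {"dm_class": [], "flex_class": []}
    for _, grp in groups.iterrows():
        gid, geno = grp["group_id"], grp["genotype"]
        members = roster.loc[roster["group_id"] == gid, "animal"].tolist()
        detections.append(
            simulate_movement(config, gid, geno, members, rngs["movement"][gid])
        )
        events.append(
            simulate_events(config, gid, geno, members, rngs["events"][gid])
        )
        phys = simulate_physiology(config, geno, members, rngs["physiology"][gid])
        phys.insert(1, "group_id", gid)
        physiology.append(phys)
        rgt_log, dm = simulate_rgt_cohort(config, geno, members, rngs["rgt"][gid])
        logs["rgt"].append(rgt_log)
        latent["dm_class"].append(dm)
        rev_log, flex = simulate_reversed_rgt(
            config, geno, members, rgt_log, rngs["reversed_rgt"][gid]
        )
        logs["reversed_rgt"].append(rev_log)
        latent["flex_class"].append(flex)
        logs["ddt"].append(
            simulate_discounting(config, geno, members, "delay", rngs["ddt"][gid])
        )
        logs["pdt"].append(
            simulate_discounting(
                config, geno, members, "probability", rngs["pdt"][gid]
            )
        )
        logs["fiext"].append(simulate_fiext(config, geno, members, rngs["fiext"][gid]))
        classical["srt"].append(simulate_srt(config, geno, members, rngs["srt"][gid]))
        classical["odor"].append(simulate_odor(config, geno, members, rngs["odor"][gid]))
        classical["dlbox"].append(
            simulate_dlbox(config, geno, members, rngs["dlbox"][gid])
        )

    task_logs = {k: pd.concat(v, ignore_index=True) for k, v in logs.items()}
    task_logs.update({k: pd.concat(v) for k, v in classical.items()})
    return SyntheticStudy(
        animals=roster,
        detections=pd.concat(detections, ignore_index=True),
        events=pd.concat(events, ignore_index=True),
        physiology=pd.concat(physiology, ignore_index=True),
        task_logs=task_logs,
        latent={k: pd.concat(v) for k, v in latent.items()},
        truth=config,
    )


def simulate_despotic_outcomes(
    n_interactions: int = 150,
    n_animals: int = 6,
    despot_win_rate: float = 0.7,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Ordered (winner, loser) interaction outcomes of a despotic group.

    One animal (``a1``) initiates/wins ``despot_win_rate`` of the group's
    agonistic interactions; the rest is uniform among the subordinates.
    """
    rng = rng or np.random.default_rng()
    animals = [f"a{i + 1}" for i in range(n_animals)]
    outcomes = []
    for _ in range(n_interactions):
        if rng.random() < despot_win_rate:
            winner = 0
            loser = int(rng.integers(1, n_animals))
        else:
            winner = int(rng.integers(1, n_animals))
            loser = int(rng.integers(n_animals - 1))
            if loser >= winner:
                loser += 1
        outcomes.append((animals[winner], animals[loser]))
    return outcomes
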