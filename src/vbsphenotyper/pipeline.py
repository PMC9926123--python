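"""End-to-end assembly of per-animal scores into the feature table.

The canonical all-animal table has the 16 profile variables:

Sexual, Weight, Corticosterone, Distance, Entropy, Defensive,
Maintenance, Aggressive, Pref.open area, Affiliative, AUC.DDT, HUB.agg,
Flexibility, RGT, Latency RGT, Blanchard

(counts are total occurrences over the 4-day stay; Weight and
Corticosterone are percent variation; Entropy is total roaming entropy
over the dark phases; HUB.agg is hub centrality in the group's general-
aggression network; Blanchard is the within-group dominance score).
Every cell must be present — the random-forest and PCA stages cannot
handle missing data — so assembly fails naming the animal and column
when a score is missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import socialnet, spatial, tasks
from .events import Window, build_dyad_matrix, count_behaviors
from .glicko import GlickoParams, final_ratings, glicko_trajectories
from .changepoint import CpdParams, detect_change_points
from .hierarchy import blanchard_score, hierarchy_metrics
from .sim import SyntheticStudy

FEATURE_COLUMNS = (
    "Sexual", "Weight", "Corticosterone", "Distance", "Entropy",
    "Defensive", "Maintenance", "Aggressive", "Pref.open area",
    "Affiliative", "AUC.DDT", "HUB.agg", "Flexibility", "RGT",
    "Latency RGT", "Blanchard",
)

#: behaviors entering the hierarchy: aggressive + sexual, dark phase, days 1-4
HIERARCHY_WINDOW = Window(days=(1, 2, 3, 4), phases=("dark",))


def interaction_outcomes(events: pd.DataFrame, window: Window = HIERARCHY_WINDOW) -> pd.DataFrame:
    """Time-ordered (winner, loser) outcomes from aggressive and sexual
    events: the initiator wins, the receiver loses."""
    from .ethogram import ETHOGRAM

    cat = events["behavior"].map(lambda b: ETHOGRAM[b].category)
    sub = events[
        window.mask(events) & cat.isin(("aggressive", "sexual")) & events["receiver"].notna()
    ].sort_values(["day", "phase", "time_s"], kind="stable")
    return pd.DataFrame(
        {"winner": sub["actor"].to_numpy(), "loser": sub["receiver"].to_numpy()}
    )


def group_hierarchy(
    events: pd.DataFrame,
    animals,
    glicko_params: GlickoParams = GlickoParams(),
    cpd_params: CpdParams = CpdParams(),
):
    """Glicko trajectories, change points and dominance metrics of one group."""
    outcomes = interaction_outcomes(events)
    ratings, deviations = glicko_trajectories(outcomes, animals, glicko_params)
    n_inter = len(outcomes)
    cps = {
        a: (detect_change_points(ratings[a].to_numpy(), cpd_params)
            if n_inter >= 2 else [])
        for a in animals
    }
    metrics = hierarchy_metrics(
        final_ratings(ratings), glicko_params,
        change_points=cps, total_group_interactions=max(n_inter, 1),
    )
    return ratings, deviations, metrics


def build_feature_table(study: SyntheticStudy) -> tuple[pd.DataFrame, pd.Series]:
    """Per-animal 16-variable feature table and genotype labels.

    Raises ``ValueError`` naming the first missing (animal, column) cell.
    """
    grid = study.truth.grid
    window = Window()
    animals = study.animals["animal"].tolist()

    cat_counts = count_behaviors(study.events, animals, window, by="category")
    for c in ("sexual", "defensive", "maintenance", "aggressive", "affiliative"):
        if c not in cat_counts.columns:
            cat_counts[c] = 0

    phys = study.physiology.set_index("animal")
    weight = tasks.physiology_changes(
        phys["weight_before_g"], phys["weight_after_g"]
    )
    cort = tasks.physiology_changes(
        phys["cort_before_ugg"], phys["cort_after_ugg"]
    )

    det = study.detections[window.mask(study.detections)]
    distance = spatial.distance_index(det, grid, per="total")
    entropy = spatial.total_roaming_entropy(study.detections, grid)
    pref_open = det.groupby("animal").apply(
        lambda g: spatial.open_area_preference(g, grid), include_groups=False
    )
    open_time = det.groupby("animal").apply(
        lambda g: spatial.open_area_time(g, grid), include_groups=False
    )

    rgt_log = study.task_logs["rgt"]
    rgt_pct, rgt_latency, flex = {}, {}, {}
    rev_log = study.task_logs["reversed_rgt"]
    for a in animals:
        a_log = rgt_log[rgt_log["animal"] == a]
        prof = tasks.rgt_profile(a_log)
        rgt_pct[a] = prof.last20_pct
        rgt_latency[a] = prof.mean_reward_latency_s
        flex[a], _ = tasks.flexibility_score(a_log, rev_log[rev_log["animal"] == a])

    ddt_curves = tasks.score_discounting_log(study.task_logs["ddt"], "delay")
    auc_ddt = {a: tasks.discounting_auc(c) for a, c in ddt_curves.items()}

    hub, blanchard = {}, {}
    for gid in study.groups["group_id"]:
        members = study.group_members(gid)
        gev = study.events[study.events["group_id"] == gid]
        dyad = build_dyad_matrix(gev, members, "general_aggression", window)
        hubs = socialnet.hub_centrality(socialnet.to_digraph(dyad))
        hub.update(hubs)
        wl = weight.loc[members, "loss"]
        blanchard.update(blanchard_score(open_time.loc[members], wl))

    table = pd.DataFrame(
        {
            "Sexual": cat_counts["sexual"],
            "Weight": weight["pct_change"],
            "Corticosterone": cort["pct_change"],
            "Distance": distance,
            "Entropy": entropy,
            "Defensive": cat_counts["defensive"],
            "Maintenance": cat_counts["maintenance"],
            "Aggressive": cat_counts["aggressive"],
            "Pref.open area": pref_open,
            "Affiliative": cat_counts["affiliative"],
            "AUC.DDT": pd.Series(auc_ddt),
            "HUB.agg": pd.Series(hub),
            "Flexibility": pd.Series(flex),
            "RGT": pd.Series(rgt_pct),
            "Latency RGT": pd.Series(rgt_latency),
            "Blanchard": pd.Series(blanchard),
        },
    ).reindex(index=animals, columns=list(FEATURE_COLUMNS))
    table.index.name = "animal"

    if table.isna().any().any():
        stacked = table.isna().stack()
        animal, column = stacked.index[stacked.to_numpy()][0]
        raise ValueError(f"missing score for animal {animal}, column {column!r}")
    labels = study.animals.set_index("animal")["genotype"].reindex(animals)
    return table, labels
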