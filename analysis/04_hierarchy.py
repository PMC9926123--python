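#!/usr/bin/env python
"""Dominance hierarchies: Glicko rating trajectories, change points,
rating contrast, Blanchard scores.

For each group, orders the dark-phase aggressive + sexual interactions,
runs the sequential Glicko rating, detects rating change points
(hierarchy stability), applies the 1/3-contrast dominance rule, and
computes the non-aggression Blanchard dominance score from open-area
time and weight loss.  Writes per-animal hierarchy variables and
per-group summaries under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from vbsphenotyper.events import Window
from vbsphenotyper.hierarchy import blanchard_score
from vbsphenotyper.pipeline import group_hierarchy, interaction_outcomes
from vbsphenotyper.sim import SimConfig, simulate_colony
from vbsphenotyper.spatial import open_area_time
from vbsphenotyper.stats import rank_sum_W, spearman
from vbsphenotyper.tasks import physiology_changes

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    study = simulate_colony(SimConfig(), seed=args.seed)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    phys = study.physiology.set_index("animal")
    weight = physiology_changes(phys["weight_before_g"], phys["weight_after_g"])
    det = study.detections[Window().mask(study.detections)]
    oa_time = det.groupby("animal").apply(
        lambda g: open_area_time(g, study.truth.grid), include_groups=False
    )

    animal_rows, group_rows = [], []
    for _, grp in study.groups.iterrows():
        gid, geno = grp["group_id"], grp["genotype"]
        ev = study.events[study.events["group_id"] == gid]
        members = study.group_members(gid)
        ratings, _, metrics = group_hierarchy(ev, members)
        n_inter = len(interaction_outcomes(ev))
        blanchard = blanchard_score(oa_time[members], weight.loc[members, "loss"])
        for a in members:
            animal_rows.append({
                "animal": a, "group_id": gid, "genotype": geno,
                "final_rating": metrics.final_ratings[a],
                "dominant": a in metrics.dominants,
                "n_change_points": len(metrics.change_points[a]),
                "norm_change_points": metrics.normalized_change_points[a],
                "blanchard": blanchard[a],
            })
        group_rows.append({
            "group_id": gid, "genotype": geno, "n_interactions": n_inter,
            "max_rating_contrast": metrics.max_rating_contrast,
            "n_dominants": len(metrics.dominants),
        })

    animals_df = pd.DataFrame(animal_rows).set_index("animal")
    groups_df = pd.DataFrame(group_rows)
    animals_df.to_csv(results / "hierarchy_animals.csv")
    groups_df.to_csv(results / "hierarchy_groups.csv", index=False)

    print(groups_df.groupby("genotype")[
        ["n_interactions", "max_rating_contrast", "n_dominants"]
    ].mean().round(2))
    wt = animals_df[animals_df["genotype"] == "wildtype"]
    ko = animals_df[animals_df["genotype"] == "knockout"]
    w, p = rank_sum_W(wt["norm_change_points"], ko["norm_change_points"])
    print(f"normalized change points: W={w:.0f} p={p:.3g}")
    rho, p = spearman(wt["final_rating"], wt["blanchard"])
    print(f"wildtype Glicko vs Blanchard: Spearman rho={rho:.2f} p={p:.3g}")


if __name__ == "__main__":
    main()
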