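"""Dominance-hierarchy summaries: rating contrast, dominants, stability,
and the non-aggression Blanchard dominance score.

The maximum rating contrast of a group is the spread between the highest
and lowest final Glicko ratings (a despotism index).  An animal is
dominant when its final rating exceeds the dominance threshold: under the
default reading, initial rating + contrast / 3 (strict inequality); an
alternative reading (group minimum + contrast / 3) is available via
``baseline='minimum'``.

The Blanchard dominance score ranks each group member 1-6 on time spent
in the open area (more time -> higher rank) and on weight loss (less loss
-> higher rank; losing weight is the submissive outcome) and averages the
two ranks; within a full group the scores always average to 3.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .glicko import GlickoParams


@dataclass(frozen=True)
class HierarchyMetrics:
    final_ratings: pd.Series
    max_rating_contrast: float
    dominants: tuple
    change_points: dict = field(default_factory=dict)
    normalized_change_points: dict = field(default_factory=dict)


def dominance_threshold(
    finals: pd.Series,
    params: GlickoParams = GlickoParams(),
    baseline: str = "initial",
) -> float:
    contrast = float(finals.max() - finals.min())
    if baseline == "initial":
        base = params.initial_rating
    elif baseline == "minimum":
        base = float(finals.min())
    else:
        raise ValueError("baseline must be 'initial' or 'minimum'")
    return base + contrast / 3.0


def hierarchy_metrics(
    finals: pd.Series,
    params: GlickoParams = GlickoParams(),
    baseline: str = "initial",
    change_points: dict | None = None,
    total_group_interactions: int | None = None,
) -> HierarchyMetrics:
    """Group-level dominance metrics from final ratings (one per animal)."""
    finals = pd.Series(finals)
    contrast = float(finals.max() - finals.min())
    thr = dominance_threshold(finals, params, baseline)
    dominants = tuple(finals.index[finals > thr])
    ncp = {}
    if change_points is not None and total_group_interactions:
        ncp = {
            a: len(cps) / total_group_interactions
            for a, cps in change_points.items()
        }
    return HierarchyMetrics(
        final_ratings=finals,
        max_rating_contrast=contrast,
        dominants=dominants,
        change_points=dict(change_points or {}),
        normalized_change_points=ncp,
    )


def blanchard_score(open_area_time, weight_loss) -> pd.Series:
    """Within-group Blanchard dominance scores (mean of two 1-6 ranks).

    Parameters
    ----------
    open_area_time : per-animal time spent in the open area (any unit).
    weight_loss : per-animal weight loss over the stay (positive = loss).

    Ties get mean ranks, so scores of a complete group of n animals
    always sum to n(n+1)/2.
    """
    oa = pd.Series(open_area_time, dtype=float)
    wl = pd.Series(weight_loss, dtype=float).reindex(oa.index)
    if oa.isna().any() or wl.isna().any():
        raise ValueError("both measures are required for every animal")
    rank_oa = rankdata(oa.to_numpy())          # more open-area time -> higher
    rank_wl = rankdata(-wl.to_numpy())         # less weight loss -> higher
    return pd.Series(
        (rank_oa + rank_wl) / 2.0, index=oa.index, name="blanchard"
    )
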