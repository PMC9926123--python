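"""Glicko rating trajectories from ordered interaction outcomes.

Each aggressive or sexual interaction is treated as one game: the
initiator is the winner (score 1), the receiver the loser (score 0), and
one rating period elapses per interaction.  Ratings follow Glickman's
update: each player carries a rating r and a rating deviation RD
(uncertainty); RD grows with inactivity by ``sqrt(RD^2 + c^2 t)`` capped
at the initial RD, shrinks with play, and scales how far a single outcome
moves the rating.

Defaults (r0 = 2200, RD0 = 300, c = 15) follow the convention of the
PlayerRatings toolkit used in the animal-dominance literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

Q = math.log(10) / 400


@dataclass(frozen=True)
class GlickoParams:
    initial_rating: float = 2200.0
    initial_deviation: float = 300.0
    c: float = 15.0


def g_factor(rd: float) -> float:
    """Attenuation of an opponent's rating by their uncertainty."""
    return 1.0 / math.sqrt(1.0 + 3.0 * Q * Q * rd * rd / math.pi**2)


def expected_score(r: float, r_opp: float, rd_opp: float) -> float:
    """Win expectancy against an opponent of rating r_opp, deviation rd_opp."""
    return 1.0 / (1.0 + 10 ** (-g_factor(rd_opp) * (r - r_opp) / 400.0))


def glicko_update(
    r: float, rd: float, r_opp: float, rd_opp: float, score: float
) -> tuple[float, float]:
    """One-period Glicko update of (r, rd) after one game against one opponent."""
    g = g_factor(rd_opp)
    e = expected_score(r, r_opp, rd_opp)
    d2 = 1.0 / (Q * Q * g * g * e * (1.0 - e))
    denom = 1.0 / (rd * rd) + 1.0 / d2
    r_new = r + (Q / denom) * g * (score - e)
    rd_new = math.sqrt(1.0 / denom)
    return r_new, rd_new


def _inflate(rd: float, periods: int, params: GlickoParams) -> float:
    if periods <= 0:
        return rd
    return min(
        math.sqrt(rd * rd + params.c**2 * periods), params.initial_deviation
    )


def glicko_trajectories(
    outcomes, animals, params: GlickoParams = GlickoParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequential ratings over a group's interaction history.

    Parameters
    ----------
    outcomes : iterable of (winner, loser) pairs in time order, or a
        DataFrame with ``winner`` / ``loser`` columns.
    animals : the group roster (animals without interactions stay at the
        initial values).

    Returns
    -------
    (ratings, deviations) : DataFrames indexed by interaction count
        0..N (row 0 = initial values), one column per animal holding that
        animal's current rating (carried forward between its games).
    """
    if isinstance(outcomes, pd.DataFrame):
        pairs = list(zip(outcomes["winner"], outcomes["loser"]))
    else:
        pairs = list(outcomes)
    animals = list(animals)
    r = {a: params.initial_rating for a in animals}
    rd = {a: params.initial_deviation for a in animals}
    last_played = {a: 0 for a in animals}
    ratings = [dict(r)]
    deviations = [dict(rd)]
    for t, (winner, loser) in enumerate(pairs, start=1):
        if winner == loser:
            raise ValueError(f"interaction {t}: winner == loser ({winner})")
        for a in (winner, loser):
            if a not in r:
                raise ValueError(f"interaction {t}: unknown animal {a!r}")
            rd[a] = _inflate(rd[a], t - 1 - last_played[a], params)
        rw, rdw = r[winner], rd[winner]
        rl, rdl = r[loser], rd[loser]
        r[winner], rd[winner] = glicko_update(rw, rdw, rl, rdl, 1.0)
        r[loser], rd[loser] = glicko_update(rl, rdl, rw, rdw, 0.0)
        last_played[winner] = last_played[loser] = t
        ratings.append(dict(r))
        deviations.append(dict(rd))
    idx = pd.RangeIndex(len(ratings), name="interaction")
    return (
        pd.DataFrame(ratings, index=idx, columns=animals),
        pd.DataFrame(deviations, index=idx, columns=animals),
    )


def final_ratings(ratings: pd.DataFrame) -> pd.Series:
    return ratings.iloc[-1].rename("final_rating")
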