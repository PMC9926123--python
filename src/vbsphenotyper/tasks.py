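"""Scores for the operant and classical tests.

Rat gambling task (RGT): the fraction of advantageous choices in the last
20 min of the 60-min session classifies animals as good decision-makers
(GDM, > 70%), poor decision-makers (PDM, < 30%) or intermediates (INT);
boundary values fall in the middle class (strict inequalities).  The mean
latency to visit the feeder after a choice indexes reward motivation.

Reversed RGT: options swap sides; the flexibility score is the percentage
of last-20-min choices on the side holding the options the animal did
not prefer in the RGT (> 60% flexible, < 40% inflexible).

Delay / probability discounting: per-level preference for the large
reward (mean of the two stable sessions) is normalized to the training
preference and integrated (trapezoid) against delay / max-delay or
odds / max-odds with odds = 1/P - 1; the x = 0 end is anchored at the
training level when no level sits there.  AUC = 1 means no discounting.

FIEXT: the session repeats two blocks of seven fixed intervals (FI) plus
one 5-min extinction (EXT); the first FI of the session and the first FI
after the first EXT are excluded, leaving 12 analyzed FIs.  Anticipatory
nose pokes are binned at 10 s within FI, perseverative pokes at 1 min
within EXT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class InsufficientDataError(ValueError):
    """A session does not contain the trials a score requires."""


SESSION_S = 3600.0
LAST20_S = SESSION_S - 1200.0


# ---------------------------------------------------------------- RGT

@dataclass(frozen=True)
class DecisionProfile:
    advantageous_pct_per_10min: list
    last20_pct: float
    dm_class: str
    mean_reward_latency_s: float


def classify_decision_maker(last20_pct: float) -> str:
    if last20_pct > 70.0:
        return "GDM"
    if last20_pct < 30.0:
        return "PDM"
    return "INT"


def rgt_profile(log: pd.DataFrame) -> DecisionProfile:
    """Score one animal's RGT session.

    ``log`` needs columns ``time_s`` (wall clock within the session),
    ``advantageous`` (bool) and ``latency_s`` (choice-to-magazine).
    """
    if len(log) == 0:
        raise InsufficientDataError("empty RGT session")
    t = log["time_s"].to_numpy(float)
    adv = log["advantageous"].to_numpy(bool)
    per_bin = []
    for b in range(6):
        m = (t >= 600 * b) & (t < 600 * (b + 1))
        per_bin.append(100.0 * adv[m].mean() if m.any() else float("nan"))
    last20 = t >= LAST20_S
    if not last20.any():
        raise InsufficientDataError("no trials in the last 20 min")
    return DecisionProfile(
        advantageous_pct_per_10min=per_bin,
        last20_pct=float(100.0 * adv[last20].mean()),
        dm_class=classify_decision_maker(float(100.0 * adv[last20].mean())),
        mean_reward_latency_s=float(log["latency_s"].mean()),
    )


def preferred_side(log: pd.DataFrame) -> str:
    """Side chosen most often during the RGT (column ``side``)."""
    if len(log) == 0:
        raise InsufficientDataError("empty RGT session")
    return log["side"].value_counts().idxmax()


def flexibility_score(
    rgt_log: pd.DataFrame, reversed_log: pd.DataFrame
) -> tuple[float, str]:
    """Percentage of last-20-min reversed-session choices on the side the
    animal did not prefer during the RGT, and the flexible / undecided /
    inflexible class (60/40 cutoffs, strict)."""
    pref = preferred_side(rgt_log)
    t = reversed_log["time_s"].to_numpy(float)
    last20 = t >= LAST20_S
    if not last20.any():
        raise InsufficientDataError("no reversed-session trials in last 20 min")
    on_other = (reversed_log["side"].to_numpy() != pref)[last20]
    score = float(100.0 * on_other.mean())
    if score > 60.0:
        cls = "flexible"
    elif score < 40.0:
        cls = "inflexible"
    else:
        cls = "undecided"
    return score, cls


# ------------------------------------------------------- discounting

def odds(p: float) -> float:
    """Odds against reward delivery: (1/P) - 1."""
    if not (0.0 < p <= 1.0):
        raise ValueError("probability must be in (0, 1]")
    return 1.0 / p - 1.0


@dataclass(frozen=True)
class DiscountingCurve:
    levels: np.ndarray          # delay (s) or probability
    preference_pct: np.ndarray  # mean of the two stable sessions, per level
    training_preference_pct: float
    kind: str                   # 'delay' or 'probability'


def score_discounting_log(log: pd.DataFrame, kind: str) -> dict:
    """Per-animal discounting curves from a trial log.

    Expects columns ``animal``, ``stage`` ('training'/'test'), ``level``,
    ``session``, ``n_trials``, ``n_large``.
    """
    curves = {}
    for animal, g in log.groupby("animal"):
        train = g[g["stage"] == "training"]
        if len(train) == 0 or train["n_trials"].sum() == 0:
            raise InsufficientDataError(f"animal {animal}: no training sessions")
        train_pct = 100.0 * train["n_large"].sum() / train["n_trials"].sum()
        test = g[g["stage"] == "test"]
        per_level = (
            test.groupby("level")
            .apply(
                lambda s: 100.0 * (s["n_large"] / s["n_trials"]).mean(),
                include_groups=False,
            )
            .sort_index()
        )
        curves[animal] = DiscountingCurve(
            levels=per_level.index.to_numpy(float),
            preference_pct=per_level.to_numpy(float),
            training_preference_pct=float(train_pct),
            kind=kind,
        )
    return curves


def discounting_auc(curve: DiscountingCurve, expected_levels=None) -> float:
    """Area under the normalized preference curve.

    x = delay / max delay, or odds / max odds (both mapped to [0, 1]);
    y = preference / training preference.  Trapezoidal rule over sorted
    x, anchoring x = 0 at the training level (y = 1) when no measured
    level sits at x = 0.
    """
    if curve.training_preference_pct <= 0:
        raise ValueError("training preference must be positive")
    if expected_levels is not None:
        missing = sorted(set(expected_levels) - set(curve.levels.tolist()))
        if missing:
            raise InsufficientDataError(f"missing levels: {missing}")
    if curve.kind == "delay":
        xraw = curve.levels.astype(float)
    elif curve.kind == "probability":
        xraw = np.array([odds(p) for p in curve.levels])
    else:
        raise ValueError("kind must be 'delay' or 'probability'")
    xmax = xraw.max()
    if xmax <= 0:
        raise ValueError("discounting needs at least one nonzero level")
    x = xraw / xmax
    y = curve.preference_pct / curve.training_preference_pct
    order = np.argsort(x)
    x, y = x[order], y[order]
    if x[0] > 0:
        x = np.concatenate(([0.0], x))
        y = np.concatenate(([1.0], y))
    return float(np.trapezoid(y, x))


# ------------------------------------------------------------- FIEXT

FI_SECONDS = 60.0
EXT_SECONDS = 300.0


def fiext_profile(log: pd.DataFrame) -> dict:
    """Anticipatory / perseverative responding in one FIEXT session.

    ``log`` has one row per nose poke: ``block`` (1 or 2), ``period_type``
    ('FI'/'EXT'), ``period_index`` (FI 1..7 within a block, EXT index 1),
    ``poke_time_s`` within the period.  The first FI of the session and
    the first FI after the first EXT are excluded.
    """
    fi = log[log["period_type"] == "FI"]
    ext = log[log["period_type"] == "EXT"]
    analyzed = ~((fi["period_index"] == 1) & fi["block"].isin((1, 2)))
    fi = fi[analyzed]
    fi_ids = [
        (b, i) for b in (1, 2) for i in range(2, 8)
    ]
    fi_totals = {
        (b, i): int(((fi["block"] == b) & (fi["period_index"] == i)).sum())
        for (b, i) in fi_ids
    }
    n_bins_fi = int(FI_SECONDS // 10)
    fi_bins = np.zeros(n_bins_fi, dtype=int)
    for tsec in fi["poke_time_s"]:
        fi_bins[min(int(tsec // 10), n_bins_fi - 1)] += 1
    n_bins_ext = int(EXT_SECONDS // 60)
    ext_bins = np.zeros(n_bins_ext, dtype=int)
    for tsec in ext["poke_time_s"]:
        ext_bins[min(int(tsec // 60), n_bins_ext - 1)] += 1
    ext_totals = {
        b: int((ext["block"] == b).sum()) for b in (1, 2)
    }
    return {
        "n_analyzed_fi": len(fi_ids),
        "fi_totals": fi_totals,
        "fi_mean": float(np.mean(list(fi_totals.values()))),
        "fi_bins_10s": fi_bins,
        "ext_totals": ext_totals,
        "ext_mean": float(np.mean(list(ext_totals.values()))),
        "ext_bins_1min": ext_bins,
    }


# -------------------------------------------- classical tests & body

def srt_scores(durations: dict) -> dict:
    """Social preference and recognition ratios from interaction times.

    ``durations`` maps encounter labels (Hab, E1..E4, Enew) to seconds of
    close interaction.  Zero denominators yield NaN (flagged missing).
    """
    def ratio(num, den):
        if durations.get(den, 0) is None or durations.get(den, 0) <= 0:
            return float("nan")
        return durations[num] / durations[den]

    return {
        "social_preference": ratio("E1", "Hab"),
        "short_term_recognition": ratio("E1", "E3"),
        "long_term_recognition": ratio("E4", "Enew"),
    }


def odor_preference(time_spoiled_s: float, time_fresh_s: float) -> float:
    """Fraction of exploration time on the social (spoiled-bedding) odor."""
    total = time_spoiled_s + time_fresh_s
    if total <= 0:
        return float("nan")
    return time_spoiled_s / total


def dlbox_risk_index(visits: pd.DataFrame) -> pd.Series:
    """Risk-taking index of a dark-light box cohort.

    Per animal: composite = duration of the first dark visit + number of
    risk assessments + total dark time; the index is the cohort maximum
    composite minus the composite, so higher = more risk-taking.
    ``visits`` needs columns ``first_dark_visit_s``, ``n_risk_assessments``,
    ``dark_time_s`` indexed by animal.
    """
    composite = (
        visits["first_dark_visit_s"]
        + visits["n_risk_assessments"]
        + visits["dark_time_s"]
    )
    return (composite.max() - composite).rename("risk_taking_index")


def physiology_changes(before: pd.Series, after: pd.Series) -> pd.DataFrame:
    """Weight / corticosterone changes from paired before-after values.

    Returns ``loss`` (before - after, positive = loss) and ``pct_change``
    (100 * (after - before) / before).
    """
    before = pd.Series(before, dtype=float)
    after = pd.Series(after, dtype=float).reindex(before.index)
    if (before <= 0).any():
        raise ValueError("baseline values must be positive")
    return pd.DataFrame(
        {
            "loss": before - after,
            "pct_change": 100.0 * (after - before) / before,
        }
    )
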