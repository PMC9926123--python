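"""Ethogram event logs: I/O, validation, counting, dyadic matrices.

An event log is a pandas DataFrame with one scan-sampled observation per
row.  Canonical columns (the CSV dialect written by the simulator and read
back by every stage):

====================  =======================================================
column                meaning
====================  =======================================================
group_id              housing-group identifier
day                   housing day, 1-based
phase                 ``dark`` or ``light``
time_s                seconds from the start of the scored phase window
actor                 focal animal id
receiver              receiving animal id, empty for solitary behaviors
behavior              ethogram label (see :mod:`vbsphenotyper.ethogram`)
duration_s            scored duration of the behavior, seconds
zone                  detector/zone index where it took place (0-based)
====================  =======================================================

Only the first four hours of each dark and each light phase are scored, so
``time_s`` lives in ``[0, 14400)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ethogram import DYADIC_CATEGORIES, ETHOGRAM

EVENT_COLUMNS = (
    "group_id", "day", "phase", "time_s", "actor", "receiver",
    "behavior", "duration_s", "zone",
)

#: seconds of video scored at the start of each phase
SCORED_PHASE_SECONDS = 4 * 3600

#: days entering every analysis (extra days of 7-day stays are retained
#: in the logs but flagged by Window.days)
ANALYSIS_DAYS = (1, 2, 3, 4)


@dataclass(frozen=True)
class Window:
    """Day/phase span selecting events (and detections) for an analysis."""

    days: tuple = ANALYSIS_DAYS
    phases: tuple = ("dark", "light")

    def mask(self, df: pd.DataFrame) -> pd.Series:
        return df["day"].isin(self.days) & df["phase"].isin(self.phases)


class EventValidationError(ValueError):
    """Raised with row numbers when an event log violates the data model."""


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check an event log against the ethogram data model.

    Returns the validated frame (with ``receiver`` NaN normalized to None
    semantics); raises :class:`EventValidationError` naming offending rows.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise EventValidationError(f"missing columns: {missing}")
    problems = []
    unknown = ~events["behavior"].isin(ETHOGRAM)
    for i in events.index[unknown]:
        problems.append(f"row {i}: unknown behavior {events.at[i, 'behavior']!r}")
    known = events[~unknown]
    cat = known["behavior"].map(lambda b: ETHOGRAM[b].category)
    has_recv = known["receiver"].notna() & (known["receiver"].astype(str) != "")
    self_dir = has_recv & (known["receiver"] == known["actor"])
    for i in known.index[self_dir]:
        problems.append(f"row {i}: actor == receiver ({events.at[i, 'actor']})")
    need_recv = cat.isin(DYADIC_CATEGORIES) & ~has_recv
    for i in known.index[need_recv]:
        problems.append(
            f"row {i}: dyadic behavior {events.at[i, 'behavior']!r} "
            "without receiver"
        )
    if (events["duration_s"] < 0).any():
        for i in events.index[events["duration_s"] < 0]:
            problems.append(f"row {i}: negative duration")
    bad_phase = ~events["phase"].isin(("dark", "light"))
    for i in events.index[bad_phase]:
        problems.append(f"row {i}: unknown phase {events.at[i, 'phase']!r}")
    if problems:
        raise EventValidationError("; ".join(problems))
    out = events.copy()
    out["receiver"] = out["receiver"].where(has_recv.reindex(out.index, fill_value=False), None)
    return out


def read_events(path) -> pd.DataFrame:
    """Read and validate an events CSV (documented header above)."""
    df = pd.read_csv(path, dtype={"group_id": str, "actor": str, "receiver": str})
    return validate_events(df)


def write_events(events: pd.DataFrame, path) -> None:
    pd.DataFrame(events, columns=list(EVENT_COLUMNS)).to_csv(path, index=False)


def count_behaviors(
    events: pd.DataFrame,
    animals,
    window: Window = Window(),
    by: str = "grouped",
) -> pd.DataFrame:
    """Per-animal occurrence counts of behaviors within a window.

    ``by='grouped'`` counts grouped labels (sniffing, general_aggression, ...);
    ``by='category'`` counts the five top-level categories.  Occurrences are
    counted, not durations (durations stay available in the log).
    """
    if by not in ("grouped", "category"):
        raise ValueError("by must be 'grouped' or 'category'")
    key = "grouped_category" if by == "grouped" else "category"
    sub = events[window.mask(events)].copy()
    sub[key] = sub["behavior"].map(
        lambda b: getattr(ETHOGRAM[b], key)
    )
    table = (
        sub.groupby(["actor", key], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=list(animals), fill_value=0)
    )
    table.index.name = "animal"
    return table.astype(int)


def most_expressed(counts: pd.DataFrame, min_median: float = 5.0) -> list:
    """Behavior labels whose cohort median count is strictly above ``min_median``."""
    med = counts.median(axis=0)
    return [c for c in counts.columns if med[c] > min_median]


@dataclass(frozen=True)
class DyadMatrix:
    """Weighted directed interaction-count matrix for one behavior category.

    ``counts[i, j]`` = number of events animal ``animals[i]`` initiated
    toward ``animals[j]`` within the window.  The diagonal is zero.
    """

    animals: tuple
    counts: np.ndarray
    category: str
    window: Window

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        n = len(self.animals)
        if c.shape != (n, n):
            raise ValueError("counts shape does not match animal list")
        if (c < 0).any() or np.diag(c).any():
            raise ValueError("counts must be non-negative with zero diagonal")

    def to_json(self) -> str:
        return json.dumps(
            {
                "animals": list(self.animals),
                "counts": self.counts.tolist(),
                "category": self.category,
                "days": list(self.window.days),
                "phases": list(self.window.phases),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "DyadMatrix":
        d = json.loads(s)
        return cls(
            tuple(d["animals"]),
            np.array(d["counts"]),
            d["category"],
            Window(tuple(d["days"]), tuple(d["phases"])),
        )


def build_dyad_matrix(
    events: pd.DataFrame,
    animals,
    category: str,
    window: Window = Window(),
    by: str = "grouped",
) -> DyadMatrix:
    """Tally directed interaction counts for one (grouped) behavior category.

    ``category`` may be a grouped label (``huddling``, ``sniffing``,
    ``general_aggression``, ``struggling_at_feeder``, ``sexual``, ...) or,
    with ``by='category'``, a top-level dyadic category.
    """
    key = "grouped_category" if by == "grouped" else "category"
    animals = list(animals)
    labels = [n for n, b in ETHOGRAM.items() if getattr(b, key) == category]
    if not labels:
        raise ValueError(f"unknown behavior category: {category!r}")
    if not any(ETHOGRAM[n].category in DYADIC_CATEGORIES for n in labels):
        raise ValueError(f"category {category!r} has no receivers (not dyadic)")
    sub = events[
        window.mask(events)
        & events["behavior"].isin(labels)
        & events["receiver"].notna()
    ]
    index = {a: i for i, a in enumerate(animals)}
    counts = np.zeros((len(animals), len(animals)), dtype=int)
    for a, r in zip(sub["actor"], sub["receiver"]):
        counts[index[a], index[r]] += 1
    return DyadMatrix(tuple(animals), counts, category, window)
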