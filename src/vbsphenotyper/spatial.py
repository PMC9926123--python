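"""Spatial metrics from RFID detection streams.

A detection stream is a pandas DataFrame of dwell intervals, one row per
uninterrupted stay at a detector:

====================  =====================================================
column                meaning
====================  =====================================================
animal                animal id
group_id              housing group
day                   housing day, 1-based
phase                 ``dark`` or ``light``
t_start_s             dwell start, seconds from phase start
duration_s            dwell length in whole seconds
detector              detector index, 0-based
====================  =====================================================

Dwells are non-overlapping within an animal.  Slicing a dwell into 1-s
detections makes longer stays weigh proportionally more, which is what the
occupancy frequencies (and hence the roaming entropy) are computed from.

Roaming entropy (RE) of an occupancy profile ``p`` over ``k`` detectors is
the normalized Shannon entropy ``RE = -sum(p log p) / log(k)`` (natural
log in both places; ``0 log 0 = 0``), so ``RE = 0`` when the animal is
always at one detector and ``RE = 1`` for uniform use of the cage.  Daily
RE uses the dark phase of each of the first four days; total RE pools the
detections of those four dark phases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import Window
from .grid import ZoneGrid

DETECTION_COLUMNS = (
    "animal", "group_id", "day", "phase", "t_start_s", "duration_s", "detector",
)

#: window the roaming-entropy analysis uses: dark phases of the first 4 days
RE_WINDOW = Window(days=(1, 2, 3, 4), phases=("dark",))


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal": str, "group_id": str})
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing detection columns: {missing}")
    return df


def write_detections(detections: pd.DataFrame, path) -> None:
    pd.DataFrame(detections, columns=list(DETECTION_COLUMNS)).to_csv(
        path, index=False
    )


def slice_detections(stream: pd.DataFrame, resolution: float = 1.0) -> pd.DataFrame:
    """Expand dwell intervals into one detection per ``resolution`` seconds.

    Raises if dwells of one animal overlap within a (day, phase).
    """
    _check_no_overlap(stream)
    reps = np.maximum(
        np.round(stream["duration_s"].to_numpy() / resolution), 0
    ).astype(int)
    out = stream.loc[stream.index.repeat(reps)].copy()
    offsets = np.concatenate([np.arange(r) for r in reps]) * resolution if len(reps) else []
    out["t_start_s"] = out["t_start_s"].to_numpy() + np.asarray(offsets)
    out["duration_s"] = resolution
    return out.reset_index(drop=True)


def _check_no_overlap(stream: pd.DataFrame) -> None:
    for (animal, day, phase), g in stream.groupby(["animal", "day", "phase"]):
        g = g.sort_values("t_start_s")
        ends = g["t_start_s"].to_numpy() + g["duration_s"].to_numpy()
        if (g["t_start_s"].to_numpy()[1:] < ends[:-1] - 1e-9).any():
            raise ValueError(
                f"overlapping dwells for animal {animal} day {day} {phase}"
            )


def occupancy_profile(stream: pd.DataFrame, k: int) -> np.ndarray:
    """Detection frequencies over the ``k`` detectors (duration-weighted).

    Equivalent to counting the 1-s slices at each detector.  Returns the
    zero vector when the stream is empty.
    """
    p = np.zeros(k)
    if len(stream) == 0:
        return p
    by_det = stream.groupby("detector")["duration_s"].sum()
    p[by_det.index.to_numpy()] = by_det.to_numpy()
    total = p.sum()
    return p / total if total > 0 else p


def roaming_entropy(p: np.ndarray, k: int | None = None) -> float:
    """Normalized Shannon entropy of an occupancy profile, in [0, 1]."""
    p = np.asarray(p, dtype=float)
    k = len(p) if k is None else k
    if k < 2:
        raise ValueError("roaming entropy needs k >= 2 detectors")
    total = p.sum()
    if total <= 0:
        return float("nan")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(k))


def daily_roaming_entropy(
    stream: pd.DataFrame, grid: ZoneGrid, window: Window = RE_WINDOW
) -> pd.DataFrame:
    """Per (animal, day) RE over the window's dark phases."""
    sub = stream[window.mask(stream)]
    rows = []
    for (animal, day), g in sub.groupby(["animal", "day"]):
        rows.append(
            {
                "animal": animal,
                "day": day,
                "re": roaming_entropy(occupancy_profile(g, grid.k)),
            }
        )
    return pd.DataFrame(rows, columns=["animal", "day", "re"])


def total_roaming_entropy(
    stream: pd.DataFrame, grid: ZoneGrid, window: Window = RE_WINDOW
) -> pd.Series:
    """Per-animal RE of detections pooled over the window's dark phases."""
    sub = stream[window.mask(stream)]
    return sub.groupby("animal").apply(
        lambda g: roaming_entropy(occupancy_profile(g, grid.k)),
        include_groups=False,
    ).rename("total_re")


def distance_index(
    stream: pd.DataFrame, grid: ZoneGrid, per: str = "total"
) -> pd.Series | pd.DataFrame:
    """Index of distance traveled: summed Euclidean distance between
    consecutive distinct detectors (arbitrary units).

    ``per='total'`` gives one number per animal; ``per='hour'`` gives
    per-animal, per (day, phase, hour) sums with hours aligned to phase
    start.
    """
    coords = grid.coordinates
    parts = []
    for (animal, day, phase), g in stream.groupby(["animal", "day", "phase"]):
        g = g.sort_values("t_start_s")
        det = g["detector"].to_numpy()
        if len(det) < 2:
            continue
        step = np.linalg.norm(coords[det[1:]] - coords[det[:-1]], axis=1)
        hour = (g["t_start_s"].to_numpy()[1:] // 3600).astype(int)
        parts.append(
            pd.DataFrame(
                {"animal": animal, "day": day, "phase": phase,
                 "hour": hour, "dist": step}
            )
        )
    if not parts:
        empty = pd.DataFrame(columns=["animal", "day", "phase", "hour", "dist"])
        return empty if per == "hour" else pd.Series(dtype=float, name="distance")
    steps = pd.concat(parts, ignore_index=True)
    if per == "hour":
        return (
            steps.groupby(["animal", "day", "phase", "hour"])["dist"]
            .sum()
            .reset_index()
        )
    return steps.groupby("animal")["dist"].sum().rename("distance")


def place_preference_maps(
    stream: pd.DataFrame,
    genotypes: dict,
    grid: ZoneGrid,
    window: Window = Window(),
) -> dict:
    """Per-genotype per-detector percent detections and their difference.

    Each animal contributes its own percent profile; a genotype's map is
    the animal-mean of those profiles (so each map sums to 100).  The
    difference map is first-genotype minus second and sums to 0.
    """
    sub = stream[window.mask(stream)]
    labels = sorted(set(genotypes.values()))
    if len(labels) != 2:
        raise ValueError("place preference maps need exactly two genotypes")
    maps = {}
    for geno in labels:
        animals = [a for a, g in genotypes.items() if g == geno]
        profiles = [
            occupancy_profile(sub[sub["animal"] == a], grid.k) for a in animals
        ]
        profiles = [p for p in profiles if p.sum() > 0]
        if not profiles:
            raise ValueError(f"no detections for genotype {geno!r}")
        maps[geno] = 100.0 * np.mean(profiles, axis=0)
    maps["difference"] = maps[labels[0]] - maps[labels[1]]
    return maps


def open_area_preference(stream: pd.DataFrame, grid: ZoneGrid) -> float:
    """Fraction of detection time spent in open-area zones, in [0, 1]."""
    total = stream["duration_s"].sum()
    if total <= 0:
        return float("nan")
    in_open = stream["detector"].isin(grid.open_area_zones)
    return float(stream.loc[in_open, "duration_s"].sum() / total)


def open_area_time(stream: pd.DataFrame, grid: ZoneGrid) -> float:
    """Seconds of detection time in open-area zones (Blanchard input)."""
    in_open = stream["detector"].isin(grid.open_area_zones)
    return float(stream.loc[in_open, "duration_s"].sum())
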