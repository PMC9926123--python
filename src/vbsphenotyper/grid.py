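"""Detector grid of the visible burrow system (VBS).

The VBS home cage is instrumented with a grid of RFID detectors placed
under the floor; every detector has a coordinate (arbitrary units, used for
the distance index) and a functional label.  The default layout is a 4 x 8
footprint of 32 detectors: one half is the uncovered open area (holding the
feeder and the water bottle), the other half is the covered burrow system,
and the two halves communicate through two tunnel rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: labels counted as "open area" (food and water are in the open area)
OPEN_AREA_LABELS = frozenset({"open_area", "feeder", "water"})

VALID_LABELS = frozenset({"open_area", "burrow", "tunnel", "feeder", "water"})


@dataclass(frozen=True)
class ZoneGrid:
    """Detector layout: coordinates, labels and adjacency.

    Parameters
    ----------
    coordinates : (k, 2) array of detector-center coordinates, arbitrary units.
    labels : per-detector functional label (see VALID_LABELS).
    adjacency : dict zone -> tuple of neighboring zones (0-based indices).
    """

    coordinates: np.ndarray
    labels: tuple
    adjacency: dict = field(repr=False)

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if self.k < 2:
            raise ValueError("a grid needs at least 2 detectors")
        if len(self.labels) != self.k:
            raise ValueError("labels and coordinates disagree on grid size")
        unknown = set(self.labels) - VALID_LABELS
        if unknown:
            raise ValueError(f"unknown zone labels: {sorted(unknown)}")
        if len({tuple(c) for c in coords}) != self.k:
            raise ValueError("detector coordinates must be unique")
        for z, nbrs in self.adjacency.items():
            if not nbrs:
                raise ValueError(f"zone {z} has no adjacent zone")
            for n in nbrs:
                if not (0 <= n < self.k):
                    raise ValueError(f"zone {z} adjacent to unknown zone {n}")

    @property
    def k(self) -> int:
        return len(self.coordinates)

    @property
    def open_area_zones(self) -> np.ndarray:
        """0-based indices of detectors in the open area (incl. feeder/water)."""
        return np.array(
            [i for i, lab in enumerate(self.labels) if lab in OPEN_AREA_LABELS]
        )

    def is_open_area(self, zone: int) -> bool:
        return self.labels[zone] in OPEN_AREA_LABELS


def default_vbs_grid() -> ZoneGrid:
    """The 32-detector VBS layout on a 4 x 8 footprint.

    Columns 0-3 form the open area (feeder at the corner next to the water
    bottle), columns 4-7 the covered burrow; the halves connect only through
    the two tunnel detectors in the top and bottom rows.
    """
    n_rows, n_cols = 4, 8
    coords = []
    labels = []
    for row in range(n_rows):
        for col in range(n_cols):
            coords.append((float(col), float(row)))
            if col <= 3:
                if (row, col) == (0, 0):
                    labels.append("feeder")
                elif (row, col) == (3, 0):
                    labels.append("water")
                else:
                    labels.append("open_area")
            elif col == 4:
                labels.append("tunnel" if row in (0, 3) else "burrow")
            else:
                labels.append("burrow")

    def idx(row, col):
        return row * n_cols + col

    adjacency = {}
    for row in range(n_rows):
        for col in range(n_cols):
            nbrs = []
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                r, c = row + dr, col + dc
                if not (0 <= r < n_rows and 0 <= c < n_cols):
                    continue
                # open/burrow halves communicate only through tunnel rows
                if {col, c} == {3, 4} and row not in (0, 3):
                    continue
                nbrs.append(idx(r, c))
            adjacency[idx(row, col)] = tuple(nbrs)
    return ZoneGrid(np.array(coords), tuple(labels), adjacency)
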