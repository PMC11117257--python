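"""Zone-occupancy time budgets for penned animals.

The pen is partitioned into named axis-aligned rectangles (defecating,
resting, eating areas; everything else is the implicit ``irrelevant``
zone).  Each identity's trajectory is gap-filled to cover every frame,
each frame's box center is classified into a zone, frames are grouped
into one-second windows labelled by majority vote, and per-zone dwell
seconds are summed into an occupancy table.  When a reference table of
manually observed durations is available, per-cell relative errors are
computed.

Eating-area correction: the box center of a feeding animal sits one
body-half behind its head, so a fixed head offset is subtracted from the
trough-side boundary — any center with ``x >= eating_boundary`` (within
the eating rectangle's y-range) counts as eating even though it lies
outside the nominal eating rectangle.

Zone rectangles are half-open (``left <= x < right``), so shared
boundaries belong to exactly one zone and classification is total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import Bbox, TrajectorySet

__all__ = [
    "ZoneMap",
    "default_zone_map",
    "fill_missing",
    "classify_point",
    "assign_seconds",
    "occupancy_summary",
    "error_analysis",
]

IRRELEVANT = "irrelevant"


@dataclass
class ZoneMap:
    """Named pixel rectangles plus the eating-area correction.

    ``zones`` maps name -> (left, top, right, bottom) corner pairs.
    ``eating_zone`` names the zone whose near boundary is corrected;
    ``eating_boundary`` is the corrected left edge (nominal left edge
    minus the head offset).
    """

    zones: Dict[str, Tuple[float, float, float, float]]
    eating_zone: Optional[str] = "eating"
    eating_boundary: Optional[float] = None
    head_offset: float = 230.0

    def __post_init__(self) -> None:
        for name, (x1, y1, x2, y2) in self.zones.items():
            if x2 <= x1 or y2 <= y1:
                raise ValueError(f"degenerate zone rectangle {name!r}")
        if self.eating_zone is not None:
            if self.eating_zone not in self.zones:
                raise ValueError(f"eating zone {self.eating_zone!r} not among zones")
            if self.eating_boundary is None:
                # the head sits ~head_offset ahead of the box center, so a
                # feeding animal's center lies that far short of the trough
                self.eating_boundary = self.zones[self.eating_zone][2] - self.head_offset
            if self.eating_boundary > self.zones[self.eating_zone][0]:
                raise ValueError("corrected eating boundary must not exceed the nominal edge")

    @property
    def zone_names(self) -> List[str]:
        return list(self.zones)


def default_zone_map() -> ZoneMap:
    """The three-zone layout of the reference 4-pig pen.

    Defecating (490,200)-(720,975), resting (720,200)-(1480,975), eating
    (1480,200)-(1580,975).  The 230 px head offset from the trough edge
    at x = 1580 puts the corrected eating boundary at x = 1350.
    """
    return ZoneMap(
        zones={
            "defecating": (490.0, 200.0, 720.0, 975.0),
            "resting": (720.0, 200.0, 1480.0, 975.0),
            "eating": (1480.0, 200.0, 1580.0, 975.0),
        },
        eating_zone="eating",
        eating_boundary=1350.0,
        head_offset=230.0,
    )


def classify_point(center: Tuple[float, float], zone_map: ZoneMap) -> str:
    """Zone name for a box center; the eating correction takes precedence."""
    x, y = center
    if zone_map.eating_zone is not None:
        _, y1, _, y2 = zone_map.zones[zone_map.eating_zone]
        if x >= zone_map.eating_boundary and y1 <= y < y2:
            return zone_map.eating_zone
    for name, (x1, y1, x2, y2) in zone_map.zones.items():
        if x1 <= x < x2 and y1 <= y < y2:
            return name
    return IRRELEVANT


def fill_missing(trajectory: Mapping[int, Bbox]) -> Dict[int, Bbox]:
    """Complete a trajectory over its observed span.

    Interior gaps are filled by linear interpolation of centers and
    sizes; there are no leading/trailing gaps within the span by
    construction (the span runs first-observation to last).
    """
    if not trajectory:
        raise ValueError("empty trajectory")
    frames = sorted(trajectory)
    arr = np.array([trajectory[f] for f in frames], dtype=float)
    full = np.arange(frames[0], frames[-1] + 1)
    out = np.empty((len(full), 4))
    for k in range(4):
        out[:, k] = np.interp(full, frames, arr[:, k])
    return {int(f): tuple(out[i]) for i, f in enumerate(full)}


def assign_seconds(
    trajectory: Mapping[int, Bbox], zone_map: ZoneMap, fps: float
) -> List[str]:
    """Label each one-second window of a gap-filled trajectory with a zone.

    Windows are consecutive blocks of ``round(fps)`` frames starting at
    the trajectory's first frame; each is labelled by the majority zone
    of its frames, ties broken toward the previous second's label (the
    earliest frame's zone for the first second).  A partial final window
    is labelled from the frames it has.
    """
    if not trajectory:
        return []
    frames = sorted(trajectory)
    window = max(int(round(fps)), 1)
    labels_per_frame = [
        classify_point(
            (trajectory[f][0] + trajectory[f][2] / 2, trajectory[f][1] + trajectory[f][3] / 2),
            zone_map,
        )
        for f in frames
    ]
    out: List[str] = []
    prev: Optional[str] = None
    for start in range(0, len(frames), window):
        chunk = labels_per_frame[start : start + window]
        counts: Dict[str, int] = {}
        for z in chunk:
            counts[z] = counts.get(z, 0) + 1
        best = max(counts.values())
        winners = [z for z, c in counts.items() if c == best]
        if len(winners) == 1:
            label = winners[0]
        elif prev in winners:
            label = prev
        else:
            label = chunk[0] if chunk[0] in winners else winners[0]
        out.append(label)
        prev = label
    return out


def occupancy_summary(
    trajectories: TrajectorySet, zone_map: ZoneMap, fps: Optional[float] = None
) -> pd.DataFrame:
    """Seconds spent per identity per zone (rows: ids; columns: zones).

    Trajectories are gap-filled first; per id, the row sums to that id's
    analyzed duration in whole seconds (including the partial final
    window, which counts as one second).
    """
    fps = trajectories.fps if fps is None else fps
    zone_cols = zone_map.zone_names + [IRRELEVANT]
    rows = {}
    for tid in trajectories.ids:
        filled = fill_missing(trajectories.trajectory(tid))
        labels = assign_seconds(filled, zone_map, fps)
        counts = {z: 0 for z in zone_cols}
        for z in labels:
            counts[z] += 1
        rows[tid] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=zone_cols).rename_axis("id")


def error_analysis(observed: pd.DataFrame, reference: pd.DataFrame) -> Dict[str, object]:
    """Relative errors (%) of an observed occupancy table vs a reference.

    Cell error is ``|observed - reference| / reference * 100``; cells
    where both are zero score 0, a positive observation against a zero
    reference is undefined (NaN).  Per-id errors are row means, per-zone
    errors are column means, the overall error is the mean of per-id
    errors.  Reported values are rounded to 2 decimals; unrounded arrays
    are returned under ``raw``.
    """
    if list(observed.index) != list(reference.index) or list(observed.columns) != list(
        reference.columns
    ):
        raise ValueError("observed and reference tables must share ids and zones")
    obs = observed.to_numpy(dtype=float)
    ref = reference.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.abs(obs - ref) / ref * 100.0
    err[(ref == 0) & (obs == 0)] = 0.0
    cells = pd.DataFrame(err, index=observed.index, columns=observed.columns)
    per_id = cells.mean(axis=1)
    per_zone = cells.mean(axis=0)
    overall = float(per_id.mean())
    return {
        "cells": cells.round(2),
        "per_id": per_id.round(2),
        "per_zone": per_zone.round(2),
        "overall": round(overall, 2),
        "raw": {"cells": cells, "per_id": per_id, "per_zone": per_zone, "overall": overall},
    }
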