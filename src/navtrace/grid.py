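"""Mobility-domain features on a square grid.

Positions are coarsened to 100 m x 100 m grid cells, which turns each
segment into a sequence (and set) of visited cell indices.  On top of
this discretisation the module computes the three mobility-domain
features: segment entropy (how spread out a participant's visits are),
pairwise segment similarity (how often routes are repeated), and the
distance of each segment from the participant's estimated home.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Trace
from .segmentation import Segment


@dataclass(frozen=True)
class GridSpec:
    """A square grid anchored at the participant's projection origin."""

    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")


@dataclass
class CellSequence:
    """A segment rendered as ordered grid-cell indices plus their set."""

    cells: np.ndarray            # (n, 2) int indices, one per sample
    cell_set: frozenset = field(init=False)

    def __post_init__(self) -> None:
        if len(self.cells) == 0:
            raise ValueError("empty cell sequence")
        self.cell_set = frozenset(map(tuple, self.cells.tolist()))


@dataclass(frozen=True)
class HomeLocation:
    participant_id: str
    xy: tuple[float, float]


def cell_indices(xy: np.ndarray, grid: GridSpec = GridSpec()) -> np.ndarray:
    """floor((coordinate - origin) / cell_size) per axis; half-open cells."""
    origin = np.asarray(grid.origin)
    return np.floor((np.asarray(xy) - origin) / grid.cell_size).astype(np.int64)


def rasterize(xy: np.ndarray, grid: GridSpec = GridSpec()) -> CellSequence:
    """Render a segment's planar samples as a grid-cell sequence."""
    return CellSequence(cells=cell_indices(xy, grid))


def segment_entropy(
    cell_sequences: list[CellSequence], per_crossing: bool = False
) -> float:
    """Shannon entropy (nats) of the pooled cell-visit distribution.

    Visit counts are pooled over all the participant's segments; by
    default every sample contributes one count, which weights cells by
    time spent.  With ``per_crossing=True`` each maximal run of
    consecutive samples in one cell counts once instead.  Cells with
    zero counts carry no mass and are simply absent from the pool.
    """
    if not cell_sequences:
        raise ValueError("need at least one cell sequence")
    counts: dict[tuple, int] = {}
    for seq in cell_sequences:
        cells = seq.cells
        if per_crossing:
            keep = np.ones(len(cells), dtype=bool)
            keep[1:] = np.any(cells[1:] != cells[:-1], axis=1)
            cells = cells[keep]
        for c in map(tuple, cells.tolist()):
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    p = np.array(list(counts.values()), dtype=float) / total
    return float(-np.sum(p * np.log(p)))


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """|A n B| / |A u B| for two nonempty cell sets."""
    if not a or not b:
        raise ValueError("cell sets must be nonempty")
    return len(a & b) / len(a | b)


def segment_similarity_fractions(
    cell_sequences: list[CellSequence], threshold: float = 0.5
) -> np.ndarray:
    """Per segment, the fraction of the other segments it is similar to.

    Two segments are *similar* when the Jaccard similarity of their cell
    sets exceeds ``threshold``.  The self-pair is excluded, so each
    fraction has denominator N - 1.  Undefined for a single segment.
    """
    n = len(cell_sequences)
    if n < 2:
        raise ValueError("similarity fractions need at least two segments")
    sets = [seq.cell_set for seq in cell_sequences]
    similar = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if jaccard(sets[i], sets[j]) > threshold:
                similar[i] += 1
                similar[j] += 1
    return similar / (n - 1)


def estimate_home(trace: Trace) -> HomeLocation:
    """Estimate home as the centroid of the daily first and last positions.

    Calendar days are resolved in UTC (the tracker's timezone).  Because
    the device is worn only when leaving the house, each recorded day
    starts and ends near the front door.
    """
    if trace.xy is None:
        raise ValueError("project the trace before estimating home")
    days = np.floor(trace.time / 86400.0).astype(np.int64)
    points = []
    for day in np.unique(days):
        idx = np.flatnonzero(days == day)
        points.append(trace.xy[idx[0]])
        points.append(trace.xy[idx[-1]])
    centre = np.mean(points, axis=0)
    return HomeLocation(trace.participant_id, (float(centre[0]), float(centre[1])))


def distance_from_home(segment_xy: np.ndarray, home: HomeLocation) -> float:
    """Euclidean distance (m) between home and the segment's centroid."""
    centroid = np.mean(segment_xy, axis=0)
    return float(np.hypot(*(centroid - np.asarray(home.xy))))


def segment_cell_sequences(
    trace: Trace, segments: list[Segment], grid: GridSpec = GridSpec()
) -> list[CellSequence]:
    return [rasterize(seg.xy(trace), grid) for seg in segments]
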