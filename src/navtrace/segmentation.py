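"""Return-loop segment extraction.

The unit of movement analysed throughout this package is the *segment*:
a contiguous sub-trajectory whose first and last samples lie within a
small slack radius of each other (the person "returns to the same
location"), lasting between 1 and 20 minutes and covering at least
100 m of path.  The duration window discards both whole-day traces and
trivial jitter loops; the length floor discards stationary noise.

Extraction is a greedy earliest-start scan within each recording bout:
at a candidate start the admissible endpoint maximising path length is
taken (ties broken towards the later endpoint), the segment is emitted,
and the scan resumes after it, so the emitted segments never overlap in
time.  Candidate endpoints are found with a KD-tree but are defined
purely by the distance predicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import Bout, Trace, UNKNOWN, majority_companionship, split_bouts


@dataclass(frozen=True)
class SegmentParams:
    """Thresholds of the loop definition (defaults: 10 m slack, 1-20 min, >=100 m)."""

    slack_radius: float = 10.0
    min_duration: float = 60.0
    max_duration: float = 1200.0
    min_length: float = 100.0

    def __post_init__(self) -> None:
        if min(self.slack_radius, self.min_duration, self.max_duration, self.min_length) <= 0:
            raise ValueError("all segment parameters must be positive")
        if not self.min_duration < self.max_duration:
            raise ValueError("min_duration must be below max_duration")


@dataclass
class Segment:
    """A return loop: half-open sample range [start, end) of one trace."""

    participant_id: str
    start: int
    end: int
    start_time: float
    end_time: float
    duration: float
    path_length: float
    companionship: str = UNKNOWN

    def __len__(self) -> int:
        return self.end - self.start

    def xy(self, trace: Trace) -> np.ndarray:
        return trace.xy[self.start : self.end]

    def times(self, trace: Trace) -> np.ndarray:
        return trace.time[self.start : self.end]


def _cumulative_length(xy: np.ndarray) -> np.ndarray:
    """cum[i] = polyline length from sample 0 to sample i."""
    steps = np.hypot(*(np.diff(xy, axis=0).T))
    return np.concatenate([[0.0], np.cumsum(steps)])


def candidate_endpoints(
    trace: Trace,
    start_index: int,
    params: SegmentParams,
    bout: Bout | None = None,
    tree: cKDTree | None = None,
) -> list[int]:
    """Indices after ``start_index`` in the same bout within the slack radius.

    Defined purely by the distance predicate
    ``|xy[j] - xy[start]| <= slack_radius``; the KD-tree only accelerates
    the search.  Returned ascending.
    """
    if trace.xy is None:
        raise ValueError("project the trace before segmentation")
    if bout is None:
        bout = next(
            b for b in split_bouts(trace) if b.start <= start_index < b.end
        )
    xy = trace.xy[bout.start : bout.end]
    if tree is None:
        tree = cKDTree(xy)
    local = start_index - bout.start
    hits = tree.query_ball_point(xy[local], params.slack_radius)
    return sorted(bout.start + j for j in hits if j > local)


def extract_segments(
    trace: Trace,
    params: SegmentParams = SegmentParams(),
    bouts: list[Bout] | None = None,
    labels: np.ndarray | None = None,
) -> list[Segment]:
    """Extract non-overlapping return-loop segments from a trace.

    Parameters
    ----------
    trace : projected trace (``xy`` filled).
    params : loop thresholds.
    bouts : recording bouts; computed with the default gap threshold when
        omitted.  Segments never span bouts.
    labels : optional per-sample companionship labels; each segment
        inherits the majority label of its samples.
    """
    if trace.xy is None:
        raise ValueError("project the trace before segmentation")
    if bouts is None:
        bouts = split_bouts(trace)

    segments: list[Segment] = []
    for bout in bouts:
        xy = trace.xy[bout.start : bout.end]
        t = trace.time[bout.start : bout.end]
        n = len(xy)
        if n < 2:
            continue
        cum = _cumulative_length(xy)
        tree = cKDTree(xy)
        i = 0
        while i < n - 1:
            hits = tree.query_ball_point(xy[i], params.slack_radius)
            best_j = -1
            best_len = -np.inf
            for j in hits:
                if j <= i:
                    continue
                dur = t[j] - t[i]
                if not (params.min_duration <= dur <= params.max_duration):
                    continue
                plen = cum[j] - cum[i]
                if plen < params.min_length:
                    continue
                if plen > best_len or (plen == best_len and j > best_j):
                    best_len, best_j = plen, j
            if best_j >= 0:
                seg = Segment(
                    participant_id=trace.participant_id,
                    start=bout.start + i,
                    end=bout.start + best_j + 1,
                    start_time=float(t[i]),
                    end_time=float(t[best_j]),
                    duration=float(t[best_j] - t[i]),
                    path_length=float(best_len),
                )
                if labels is not None:
                    seg.companionship = majority_companionship(
                        labels[seg.start : seg.end]
                    )
                segments.append(seg)
                i = best_j + 1
            else:
                i += 1

    _assert_valid(segments, trace, params)
    return segments


def _assert_valid(
    segments: list[Segment], trace: Trace, params: SegmentParams
) -> None:
    """Re-check every emitted segment against the four loop predicates."""
    prev_end = -1
    for seg in sorted(segments, key=lambda s: s.start):
        if seg.start < prev_end:
            raise AssertionError("overlapping segments emitted")
        prev_end = seg.end
        closure = float(np.hypot(*(trace.xy[seg.end - 1] - trace.xy[seg.start])))
        if closure > params.slack_radius * (1 + 1e-9):
            raise AssertionError("segment endpoints exceed slack radius")
        if not params.min_duration <= seg.duration <= params.max_duration:
            raise AssertionError("segment duration outside window")
        if seg.path_length < params.min_length * (1 - 1e-9):
            raise AssertionError("segment shorter than minimum length")
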