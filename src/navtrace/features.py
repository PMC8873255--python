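"""Per-participant analysis and feature-vector assembly.

`analyze_participant` runs the full single-participant chain — project,
split bouts, label companionship, extract return loops, compute per-
segment features, build the mobility graph — and keeps the raw results.
`build_features` then condenses an analysis into the participant
feature vector used by group statistics and classification: scalars
(entropy, graph node count) plus raw value lists that are rendered as
normalised histograms at classification time, with histogram ranges
frozen on the training participants of each fold so the held-out
participant leaks nothing into the representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import graph as graph_mod
from .config import RunConfig
from .grid import (
    GridSpec,
    distance_from_home,
    estimate_home,
    segment_cell_sequences,
    segment_similarity_fractions,
    segment_entropy,
)
from .io import ALONE, OutingAnnotation, Trace, label_companionship, project_to_plane, split_bouts
from .segmentation import Segment, SegmentParams, extract_segments
from .shape import (
    detect_stops,
    radius_of_gyration,
    segment_complexity,
    total_turning_angle,
    turning_angles,
)
from .stats import make_histogram

logger = logging.getLogger(__name__)

#: Features carried as single scalars; everything else is a value list
#: represented as a normalised histogram.
SCALAR_FEATURES = ("entropy", "node_count")

#: Per-segment value-list features available for participant vectors.
HISTOGRAM_FEATURES = (
    "segment_similarity",
    "distance_from_home",
    "stop_durations",
    "complexity",
    "total_turning_angle",
    "radius_of_gyration",
    "n_stops",
    "closeness",
    "betweenness",
    "degree_centrality",
)


@dataclass
class ParticipantAnalysis:
    """Raw per-participant results of the full analysis chain."""

    participant_id: str
    group: str
    trace: Trace
    segments: list[Segment]
    seg_table: pd.DataFrame
    stop_durations: list[list[float]]
    home: tuple[float, float]
    node_count: int | None = None
    centralities: "graph_mod.CentralityTable | None" = None
    graph: object | None = None


def analyze_participant(
    trace: Trace,
    annotations: list[OutingAnnotation] | None = None,
    cfg: RunConfig = RunConfig(),
    with_graph: bool = True,
) -> ParticipantAnalysis:
    """Run segmentation, per-segment features and the mobility graph."""
    if trace.xy is None:
        trace = project_to_plane(trace)
    bouts = split_bouts(trace, cfg.gap_threshold)
    labels = label_companionship(trace, annotations) if annotations else None
    params = SegmentParams(
        slack_radius=cfg.slack_radius,
        min_duration=cfg.min_duration,
        max_duration=cfg.max_duration,
        min_length=cfg.min_length,
    )
    segments = extract_segments(trace, params, bouts=bouts, labels=labels)
    home = estimate_home(trace)

    rows = []
    stop_lists: list[list[float]] = []
    for k, seg in enumerate(segments):
        xy = seg.xy(trace)
        ang = turning_angles(xy)
        stops = detect_stops(
            seg.times(trace), xy, cfg.static_radius, cfg.min_stop_duration
        )
        stop_lists.append(stops.durations)
        rows.append(
            {
                "segment_id": k,
                "start_time": seg.start_time,
                "end_time": seg.end_time,
                "duration_s": seg.duration,
                "path_length_m": seg.path_length,
                "companionship": seg.companionship,
                "complexity": segment_complexity(ang, cfg.complexity_threshold),
                "total_turning_angle": total_turning_angle(ang),
                "radius_of_gyration": radius_of_gyration(xy),
                "n_stops": stops.count,
                "total_stop_duration": float(sum(stops.durations)),
                "distance_from_home": distance_from_home(xy, home),
            }
        )
    seg_table = pd.DataFrame(
        rows,
        columns=[
            "segment_id", "start_time", "end_time", "duration_s",
            "path_length_m", "companionship", "complexity",
            "total_turning_angle", "radius_of_gyration", "n_stops",
            "total_stop_duration", "distance_from_home",
        ],
    )

    analysis = ParticipantAnalysis(
        participant_id=trace.participant_id,
        group=trace.group,
        trace=trace,
        segments=segments,
        seg_table=seg_table,
        stop_durations=stop_lists,
        home=home.xy,
    )
    if with_graph:
        grid = GridSpec(cell_size=cfg.cell_size)
        G = graph_mod.build_graph(trace, grid, cfg.dwell_threshold, bouts=bouts)
        analysis.graph = G
        analysis.node_count = G.number_of_nodes()
        if analysis.node_count >= 2:
            analysis.centralities = graph_mod.centralities(G)
    return analysis


@dataclass
class ParticipantFeatures:
    """Scalars plus raw value lists for one participant and segment subset."""

    participant_id: str
    group: str
    n_segments: int
    n_alone_segments: int
    node_count: int | None
    scalars: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)


def build_features(
    analysis: ParticipantAnalysis,
    cfg: RunConfig = RunConfig(),
    segment_filter: str = "all",
) -> ParticipantFeatures | None:
    """Condense an analysis into a participant feature vector.

    ``segment_filter`` selects which segments contribute: ``"all"`` or
    ``"alone"`` (diary-labelled alone segments, used for patients in the
    spatiotemporal task).  Entropy and similarity are recomputed on the
    selected subset.  Returns None (logged) when fewer than two segments
    remain, since segment similarity is undefined for one segment.
    """
    tab = analysis.seg_table
    n_alone = int((tab["companionship"] == ALONE).sum()) if len(tab) else 0
    if segment_filter == "all":
        mask = np.ones(len(tab), dtype=bool)
    elif segment_filter == "alone":
        mask = (tab["companionship"] == ALONE).to_numpy()
    else:
        raise ValueError(f"unknown segment filter {segment_filter!r}")
    idx = np.flatnonzero(mask)
    if len(idx) < 2:
        logger.warning(
            "%s: %d segments after %r filter, feature vector undefined",
            analysis.participant_id, len(idx), segment_filter,
        )
        return None

    segs = [analysis.segments[i] for i in idx]
    grid = GridSpec(cell_size=cfg.cell_size)
    seqs = segment_cell_sequences(analysis.trace, segs, grid)
    sub = tab.iloc[idx]

    feats = ParticipantFeatures(
        participant_id=analysis.participant_id,
        group=analysis.group,
        n_segments=len(idx),
        n_alone_segments=n_alone,
        node_count=analysis.node_count,
    )
    feats.scalars["entropy"] = segment_entropy(seqs)
    if analysis.node_count is not None:
        feats.scalars["node_count"] = float(analysis.node_count)
    feats.values["segment_similarity"] = segment_similarity_fractions(
        seqs, cfg.jaccard_threshold
    )
    feats.values["distance_from_home"] = sub["distance_from_home"].to_numpy()
    feats.values["complexity"] = sub["complexity"].to_numpy(dtype=float)
    feats.values["total_turning_angle"] = sub["total_turning_angle"].to_numpy()
    feats.values["radius_of_gyration"] = sub["radius_of_gyration"].to_numpy()
    feats.values["n_stops"] = sub["n_stops"].to_numpy(dtype=float)
    stops = [d for i in idx for d in analysis.stop_durations[i]]
    feats.values["stop_durations"] = np.asarray(stops, dtype=float)
    if analysis.centralities is not None:
        feats.values["closeness"] = analysis.centralities.closeness
        feats.values["betweenness"] = analysis.centralities.betweenness
        feats.values["degree_centrality"] = analysis.centralities.degree
    return feats


def pooled_values(
    feats: list[ParticipantFeatures], name: str
) -> np.ndarray:
    """Pool a value-list feature over participants (aggregate distributions)."""
    if name == "entropy":
        return np.array([f.scalars["entropy"] for f in feats])
    if name == "node_count":
        return np.array([f.scalars["node_count"] for f in feats])
    parts = [f.values[name] for f in feats if name in f.values]
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def assemble_design(
    feats: list[ParticipantFeatures],
    subset: list[str],
    bins: int,
    train_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Build the classification design matrix for one cross-validation fold.

    Histogram features use bin ranges spanning the pooled *training*
    values; scalar features are z-scored with training mean and SD.
    Rows are returned for all participants (training statistics applied
    to held-out rows as well).  ``y`` is 1 for controls.
    """
    if not subset:
        raise ValueError("empty feature subset")
    train_idx = np.asarray(train_idx)
    columns: list[np.ndarray] = []
    for name in subset:
        if name in SCALAR_FEATURES:
            vals = np.array([f.scalars[name] for f in feats])
            mu = vals[train_idx].mean()
            sd = vals[train_idx].std()
            columns.append(((vals - mu) / (sd if sd > 0 else 1.0))[:, None])
        else:
            pooled = np.concatenate([feats[i].values[name] for i in train_idx])
            if pooled.size == 0:
                lo, hi = 0.0, 1.0
            else:
                lo, hi = float(pooled.min()), float(pooled.max())
                if not lo < hi:
                    hi = lo + 1.0
            rows = [
                make_histogram(f.values[name], bins=bins, value_range=(lo, hi))
                if len(f.values[name])
                else np.zeros(bins)
                for f in feats
            ]
            columns.append(np.vstack(rows))
    X = np.hstack(columns)
    y = np.array([1.0 if f.group == "control" else 0.0 for f in feats])
    return X, y
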