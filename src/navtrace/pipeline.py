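"""End-to-end orchestration: ingest -> segment -> features -> graphs ->
group statistics -> classification -> report bundle.

Every stage writes a CSV table into the output directory; the run ends
with a machine-readable ``summary.json`` and a snapshot of the
configuration.  All stochastic steps are seeded from the configuration's
master seed, so a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import classify_alone_accompanied, feature_combination_report
from .config import RunConfig
from .features import (
    ParticipantAnalysis,
    ParticipantFeatures,
    analyze_participant,
    build_features,
    pooled_values,
)
from .io import ACCOMPANIED, ALONE, Trace, read_annotations, read_metadata, read_trace
from .stats import apply_cohort_filters, compare_groups

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

SPATIOTEMPORAL_COMPARISON = (
    "segment_similarity",
    "entropy",
    "distance_from_home",
    "stop_durations",
    "complexity",
    "total_turning_angle",
    "radius_of_gyration",
)

ALONE_COMPARISON = ("complexity", "total_turning_angle", "n_stops", "distance_from_home")

GRAPH_COMPARISON = ("node_count", "closeness", "betweenness", "degree_centrality")

#: Feature combinations reported for the patient-vs-control task.
DEFAULT_LOO_SUBSETS = (
    ("entropy",),
    ("segment_similarity",),
    ("stop_durations",),
    ("distance_from_home",),
    ("complexity",),
    ("segment_similarity", "entropy"),
    ("stop_durations", "entropy"),
    ("segment_similarity", "stop_durations", "entropy"),
    ("segment_similarity", "entropy", "distance_from_home"),
    ("segment_similarity", "entropy", "complexity"),
)

DEFAULT_GRAPH_SUBSETS = (
    ("node_count",),
    ("closeness",),
    ("betweenness",),
    ("degree_centrality",),
    ("node_count", "closeness", "betweenness", "degree_centrality"),
    (
        "segment_similarity",
        "entropy",
        "node_count",
        "closeness",
        "betweenness",
        "degree_centrality",
    ),
)

DEFAULT_SVM_SUBSETS = (
    ("complexity",),
    ("total_turning_angle",),
    ("n_stops",),
    ("distance_from_home",),
    ("complexity", "total_turning_angle"),
)


def load_cohort_dir(input_dir: str | Path):
    """Read metadata, annotations and all trace files from a cohort directory."""
    input_dir = Path(input_dir)
    meta_path = input_dir / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file {meta_path}")
    metadata = read_metadata(meta_path)
    ann_path = input_dir / "annotations.csv"
    annotations = read_annotations(ann_path) if ann_path.exists() else {}
    traces: list[Trace] = []
    for pid in sorted(metadata):
        for candidate in (
            input_dir / "traces" / f"{pid}.csv",
            input_dir / "traces" / f"{pid}.gpx",
        ):
            if candidate.exists():
                traces.append(read_trace(candidate, pid, metadata[pid]))
                break
        else:
            raise FileNotFoundError(f"no trace file for participant {pid}")
    return traces, metadata, annotations


@dataclass
class CohortAnalysis:
    """All per-participant analyses plus the task-level feature sets."""

    cfg: RunConfig
    analyses: list[ParticipantAnalysis]
    spatiotemporal: list[ParticipantFeatures] = field(default_factory=list)
    graph_task: list[ParticipantFeatures] = field(default_factory=list)


def analyze_cohort(
    traces: list[Trace],
    annotations: dict[str, list],
    cfg: RunConfig = RunConfig(),
    with_graph: bool = True,
) -> CohortAnalysis:
    """Run the per-participant chain and assemble the two task cohorts.

    Participants with zero segments are excluded (logged).  The
    spatiotemporal task keeps controls with all segments and patients
    with >5 alone segments (alone segments only); the graph task keeps
    participants with at least ten graph nodes.
    """
    analyses = []
    for trace in traces:
        analysis = analyze_participant(
            trace, annotations.get(trace.participant_id), cfg, with_graph=with_graph
        )
        if not analysis.segments:
            logger.warning("%s: no segments extracted, excluded", trace.participant_id)
            continue
        analyses.append(analysis)

    spatio: list[ParticipantFeatures] = []
    for a in analyses:
        f = build_features(a, cfg, "all" if a.group == "control" else "alone")
        if f is not None:
            spatio.append(f)
    spatio = apply_cohort_filters(spatio, "spatiotemporal")

    graph_task: list[ParticipantFeatures] = []
    if with_graph:
        for a in analyses:
            f = build_features(a, cfg, "all")
            if f is not None:
                graph_task.append(f)
        graph_task = [f for f in graph_task if f.node_count is not None]
        graph_task = apply_cohort_filters(graph_task, "graph")

    return CohortAnalysis(cfg=cfg, analyses=analyses, spatiotemporal=spatio, graph_task=graph_task)


def segments_table(result: CohortAnalysis) -> pd.DataFrame:
    frames = []
    for a in result.analyses:
        tab = a.seg_table.copy()
        tab.insert(0, "participant_id", a.participant_id)
        tab.insert(1, "group", a.group)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def participants_table(result: CohortAnalysis) -> pd.DataFrame:
    rows = []
    for a in result.analyses:
        f = build_features(a, result.cfg, "all")
        rows.append(
            {
                "participant_id": a.participant_id,
                "group": a.group,
                "n_segments": len(a.segments),
                "n_alone_segments": int((a.seg_table["companionship"] == ALONE).sum()),
                "entropy": f.scalars["entropy"] if f else np.nan,
                "node_count": a.node_count if a.node_count is not None else np.nan,
                "home_x": a.home[0],
                "home_y": a.home[1],
            }
        )
    return pd.DataFrame(rows)


def spatiotemporal_comparison(result: CohortAnalysis) -> pd.DataFrame:
    """Control-vs-patient KS/effect-size table on the alone-filtered cohort."""
    controls = [f for f in result.spatiotemporal if f.group == "control"]
    patients = [f for f in result.spatiotemporal if f.group == "patient"]
    if not controls or not patients:
        logger.warning("group comparison skipped: a group has no eligible participants")
        return pd.DataFrame(columns=["feature", "ks_statistic", "p_value", "cohens_d"])
    pooled = {
        name: (pooled_values(controls, name), pooled_values(patients, name))
        for name in SPATIOTEMPORAL_COMPARISON
    }
    return compare_groups(pooled)


def alone_accompanied_comparison(result: CohortAnalysis) -> pd.DataFrame:
    """Alone-vs-accompanied KS table on pooled patient segments."""
    seg = segments_table(result)
    seg = seg[(seg["group"] == "patient") & seg["companionship"].isin([ALONE, ACCOMPANIED])]
    pooled = {}
    for name in ALONE_COMPARISON:
        a = seg.loc[seg["companionship"] == ALONE, name].to_numpy(dtype=float)
        b = seg.loc[seg["companionship"] == ACCOMPANIED, name].to_numpy(dtype=float)
        if len(a) and len(b):
            pooled[name] = (a, b)
    return compare_groups(pooled)


def graph_comparison(result: CohortAnalysis) -> pd.DataFrame:
    controls = [f for f in result.graph_task if f.group == "control"]
    patients = [f for f in result.graph_task if f.group == "patient"]
    if not controls or not patients:
        return pd.DataFrame(columns=["feature", "ks_statistic", "p_value", "cohens_d"])
    pooled = {
        name: (pooled_values(controls, name), pooled_values(patients, name))
        for name in GRAPH_COMPARISON
    }
    return compare_groups(pooled)


def _enough_for_loo(feats: list[ParticipantFeatures]) -> bool:
    return (
        sum(f.group == "control" for f in feats) >= 2
        and sum(f.group == "patient" for f in feats) >= 2
    )


def patient_segment_matrix(
    result: CohortAnalysis, subset: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-segment features and labels for the alone/accompanied task."""
    seg = segments_table(result)
    seg = seg[(seg["group"] == "patient") & seg["companionship"].isin([ALONE, ACCOMPANIED])]
    X = seg[list(subset)].to_numpy(dtype=float)
    y = (seg["companionship"] == ALONE).to_numpy(dtype=int)
    return X, y


def run_pipeline(
    cfg: RunConfig,
    input_dir: str | Path,
    output_dir: str | Path,
    loo_subsets=DEFAULT_LOO_SUBSETS,
    graph_subsets=DEFAULT_GRAPH_SUBSETS,
    svm_subsets=DEFAULT_SVM_SUBSETS,
) -> dict:
    """Run the full analysis on a cohort directory; returns the summary dict."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces, metadata, annotations = load_cohort_dir(input_dir)
    result = analyze_cohort(traces, annotations, cfg)

    seg = segments_table(result)
    seg.to_csv(out / "segments.csv", index=False, float_format=FLOAT_FMT)
    participants_table(result).to_csv(
        out / "participants.csv", index=False, float_format=FLOAT_FMT
    )

    comp_st = spatiotemporal_comparison(result)
    comp_st.to_csv(
        out / "group_comparison_spatiotemporal.csv", index=False, float_format=FLOAT_FMT
    )
    comp_aa = alone_accompanied_comparison(result)
    comp_aa.to_csv(
        out / "group_comparison_alone_accompanied.csv", index=False, float_format=FLOAT_FMT
    )
    comp_g = graph_comparison(result)
    comp_g.to_csv(out / "group_comparison_graph.csv", index=False, float_format=FLOAT_FMT)

    summary: dict = {
        "n_participants": len(result.analyses),
        "n_segments": int(len(seg)),
        "spatiotemporal_comparison": comp_st.to_dict("records"),
        "alone_accompanied_comparison": comp_aa.to_dict("records"),
        "graph_comparison": comp_g.to_dict("records"),
    }

    seeds = np.random.SeedSequence(cfg.master_seed).spawn(3)
    loo_kwargs = dict(
        runs=cfg.runs,
        sgd_steps=cfg.sgd_steps,
        learning_rate=cfg.learning_rate,
        bins=cfg.bins,
    )

    if _enough_for_loo(result.spatiotemporal):
        report = feature_combination_report(
            result.spatiotemporal, [list(s) for s in loo_subsets],
            seed=seeds[0], **loo_kwargs,
        )
        report.to_csv(out / "loo_report.csv", index=False, float_format=FLOAT_FMT)
        summary["loo_report"] = report.to_dict("records")
    else:
        logger.warning("spatiotemporal classification skipped: insufficient participants")
        summary["loo_report"] = None

    if _enough_for_loo(result.graph_task):
        report = feature_combination_report(
            result.graph_task, [list(s) for s in graph_subsets],
            seed=seeds[1], **loo_kwargs,
        )
        report.to_csv(out / "graph_loo_report.csv", index=False, float_format=FLOAT_FMT)
        summary["graph_loo_report"] = report.to_dict("records")
    else:
        logger.warning("graph classification skipped: insufficient participants")
        summary["graph_loo_report"] = None

    svm_rows = []
    X_all, y_all = patient_segment_matrix(result, ALONE_COMPARISON)
    n_alone = int((y_all == 1).sum())
    n_acc = int((y_all == 0).sum())
    if min(n_alone, n_acc) >= 10:
        svm_seeds = seeds[2].spawn(len(svm_subsets))
        for subset, s in zip(svm_subsets, svm_seeds):
            X, y = patient_segment_matrix(result, subset)
            res = classify_alone_accompanied(
                X, y, cfg.test_fraction, cfg.repeats, seed=s
            )
            svm_rows.append(
                {"features": "+".join(subset), "median_accuracy": res.median_accuracy}
            )
        pd.DataFrame(svm_rows).to_csv(
            out / "alone_accompanied_report.csv", index=False, float_format=FLOAT_FMT
        )
        summary["alone_accompanied_report"] = svm_rows
    else:
        logger.warning(
            "alone/accompanied classification skipped: %d alone vs %d accompanied",
            n_alone, n_acc,
        )
        summary["alone_accompanied_report"] = None

    (out / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=2, sort_keys=True)
    )
    (out / "config.json").write_text(cfg.to_json())
    return summary


def _jsonable(obj):
    """Recursively convert numpy scalars and non-finite floats for JSON."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        return float(obj) if np.isfinite(obj) else None
    return obj


def bin_sweep(
    cfg: RunConfig,
    input_dir: str | Path,
    bins_list: list[int],
    subset: tuple[str, ...] = ("segment_similarity", "stop_durations", "entropy"),
) -> pd.DataFrame:
    """Rerun the leave-one-out task for several histogram bin counts.

    Seeds are identical across settings so only the representation
    changes.  Duplicate entries in ``bins_list`` are flagged.
    """
    rows = []
    if not bins_list:
        return pd.DataFrame(columns=["bins", "features", "median_sensitivity",
                                     "median_specificity", "uncertainty", "duplicate"])
    traces, metadata, annotations = load_cohort_dir(input_dir)
    result = analyze_cohort(traces, annotations, cfg, with_graph=False)
    seen = set()
    seed = np.random.SeedSequence(cfg.master_seed).spawn(1)[0]
    for bins in bins_list:
        rep = feature_combination_report(
            result.spatiotemporal, [list(subset)],
            runs=cfg.runs, sgd_steps=cfg.sgd_steps,
            learning_rate=cfg.learning_rate, bins=bins, seed=seed,
        )
        row = rep.iloc[0].to_dict()
        row["bins"] = bins
        row["duplicate"] = bins in seen
        if row["duplicate"]:
            logger.warning("bins=%d appears more than once in the sweep", bins)
        seen.add(bins)
        rows.append(row)
    return pd.DataFrame(rows)[
        ["bins", "features", "median_sensitivity", "median_specificity",
         "uncertainty", "duplicate"]
    ]
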