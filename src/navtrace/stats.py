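"""Group-level statistics: histograms, KS tests, effect sizes, cohort filters.

Per-segment (or per-node) feature values are pooled across the
participants of each group and compared with the two-sample
Kolmogorov-Smirnov test; effect sizes are Cohen's d with the pooled
standard deviation.  Participant feature vectors for classification
represent value lists as fixed-range normalised histograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


def make_histogram(
    values, bins: int = 10, value_range: tuple[float, float] = (0.0, 1.0)
) -> np.ndarray:
    """Normalised counts over equal-width bins on ``value_range``.

    Bins are half-open with the last bin closed (numpy convention);
    values outside the range are clipped into the terminal bins so that
    the total count is conserved.  The output sums to 1.
    """
    lo, hi = value_range
    if not lo < hi:
        raise ValueError("histogram range must have lo < hi")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot histogram an empty value list")
    counts, _ = np.histogram(np.clip(values, lo, hi), bins=bins, range=(lo, hi))
    return counts / counts.sum()


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample KS statistic and asymptotic p-value.

    The statistic is the maximum separation of the two empirical CDFs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def cohens_d(a, b) -> float:
    """(mean(a) - mean(b)) / pooled SD, with the (n-1)-weighted pooled variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("Cohen's d needs at least two values per sample")
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(s2))


@dataclass
class GroupComparison:
    feature: str
    ks_statistic: float
    p_value: float
    cohens_d: float


def compare_groups(
    pooled: dict[str, tuple[np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """One KS + Cohen's d row per feature.

    ``pooled`` maps a feature name to its two pooled value arrays
    (first group, second group); d is signed as first minus second.
    """
    rows = []
    for name, (a, b) in pooled.items():
        stat, p = ks_two_sample(a, b)
        try:
            d = cohens_d(a, b)
        except ValueError:
            d = np.nan
        rows.append(
            {"feature": name, "ks_statistic": stat, "p_value": p, "cohens_d": d}
        )
    return pd.DataFrame(rows, columns=["feature", "ks_statistic", "p_value", "cohens_d"])


def apply_cohort_filters(participants: list, task: str) -> list:
    """Apply the published cohort filters for a classification task.

    ``task="spatiotemporal"``: controls keep all segments; patients are
    restricted to the segments made while moving alone and must have
    strictly more than five of them.  ``task="graph"``: participants
    need at least ten nodes in their mobility graphs; all segments are
    retained.  ``participants`` is a list of objects exposing ``group``,
    ``n_alone_segments`` and ``node_count`` (see features module); the
    returned list preserves order.
    """
    if task not in ("spatiotemporal", "graph"):
        raise ValueError(f"unknown task {task!r}")
    kept = []
    for p in participants:
        if task == "spatiotemporal":
            if p.group == "patient" and p.n_alone_segments <= 5:
                logger.info(
                    "%s excluded: %d alone segments (need >5)",
                    p.participant_id,
                    p.n_alone_segments,
                )
                continue
        elif task == "graph":
            if p.node_count is None or p.node_count < 10:
                logger.info(
                    "%s excluded: graph has %s nodes (need >=10)",
                    p.participant_id,
                    p.node_count,
                )
                continue
        kept.append(p)
    return kept
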