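"""Shared fixtures and independent reference implementations (oracles).

The oracles deliberately re-derive each quantity by the most direct
method available — exhaustive enumeration, literal formula evaluation —
and share no code with the package internals they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from navtrace import CohortConfig, RunConfig, Trace, generate_cohort, write_cohort
from navtrace.segmentation import Segment, SegmentParams


# ------------------------------------------------------------- builders


def trace_from_xy(
    xy, times=None, participant_id="T00", group="control", dt=3.0
) -> Trace:
    """A Trace with planar coordinates injected directly (unit-test shortcut)."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if times is None:
        times = np.arange(n) * dt
    return Trace(
        participant_id=participant_id,
        group=group,
        time=np.asarray(times, dtype=float),
        lat=np.zeros(n),
        lon=np.zeros(n),
        sampling_interval=dt,
        xy=xy,
    )


def recurrent_walk(rng, n, dt=3.0, pull=0.985, step_sd=9.0):
    """A mean-reverting random walk: wanders out and keeps returning,
    so return loops of every size occur."""
    xy = np.zeros((n, 2))
    for i in range(1, n):
        xy[i] = pull * xy[i - 1] + rng.normal(0.0, step_sd, 2)
    return trace_from_xy(xy, np.arange(n) * dt)


# -------------------------------------------------------------- oracles


def haversine_m(lat1, lon1, lat2, lon2, radius=6371008.8):
    """Great-circle distance, literal haversine formula."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * radius * math.asin(math.sqrt(a))


def brute_extract_segments(trace: Trace, params: SegmentParams, bouts) -> list[tuple]:
    """O(n^2) reference for return-loop extraction.

    Enumerates every (i, j) pair directly from the distance predicate
    and applies the same greedy policy (earliest start, maximum path
    length, ties to the later endpoint, resume after the loop).
    Returns (start, end) index spans.
    """
    spans = []
    for bout in bouts:
        xy = trace.xy[bout.start : bout.end]
        t = trace.time[bout.start : bout.end]
        n = len(xy)
        if n < 2:
            continue
        step = np.hypot(*np.diff(xy, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(step)])
        i = 0
        while i < n - 1:
            d = np.hypot(*(xy[i + 1 :] - xy[i]).T)
            best_j, best_len = -1, -np.inf
            for off in np.flatnonzero(d <= params.slack_radius):
                j = i + 1 + int(off)
                dur = t[j] - t[i]
                if not (params.min_duration <= dur <= params.max_duration):
                    continue
                plen = cum[j] - cum[i]
                if plen < params.min_length:
                    continue
                if plen > best_len or (plen == best_len and j > best_j):
                    best_len, best_j = plen, j
            if best_j >= 0:
                spans.append((bout.start + i, bout.start + best_j + 1))
                i = best_j + 1
            else:
                i += 1
    return spans


def brute_stops(times, xy, static_radius, min_stop_duration):
    """Literal anchored-window stop scan with plain loops."""
    times = np.asarray(times, float)
    xy = np.asarray(xy, float)
    n = len(times)
    out = []
    i = 0
    while i < n:
        j = i + 1
        while j < n and math.hypot(*(xy[j] - xy[i])) <= static_radius:
            j += 1
        span = times[j - 1] - times[i]
        if span >= min_stop_duration:
            out.append(span)
            i = j
        else:
            i += 1
    return out


def brute_ks_statistic(a, b):
    """sup |F1 - F2| evaluated at every pooled sample point."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    best = 0.0
    for x in np.concatenate([a, b]):
        f1 = np.mean(a <= x)
        f2 = np.mean(b <= x)
        best = max(best, abs(f1 - f2))
    return best


def brute_centralities(G):
    """All-pairs-BFS closeness / betweenness / degree on a small graph.

    Closeness uses the component-scaled (Wasserman-Faust) formula;
    betweenness counts shortest paths by dynamic programming over the
    BFS layer DAG and normalises by (n-1)(n-2)/2.
    """
    nodes = sorted(G.nodes)
    n = len(nodes)
    index = {v: k for k, v in enumerate(nodes)}
    INF = float("inf")
    dist = np.full((n, n), INF)
    sigma = np.zeros((n, n))  # number of shortest paths
    for s in nodes:
        si = index[s]
        dist[si, si] = 0
        sigma[si, si] = 1.0
        layer = [s]
        d = 0
        while layer:
            nxt = []
            for u in layer:
                for w in G.neighbors(u):
                    wi = index[w]
                    if dist[si, wi] == INF:
                        dist[si, wi] = d + 1
                        nxt.append(w)
                    if dist[si, wi] == d + 1:
                        sigma[si, wi] += sigma[si, index[u]]
            layer = list(dict.fromkeys(nxt))
            d += 1
    closeness = np.zeros(n)
    for vi in range(n):
        reach = [u for u in range(n) if u != vi and dist[vi, u] < INF]
        if reach:
            total = sum(dist[vi, u] for u in reach)
            closeness[vi] = (len(reach) / total) * (len(reach) / (n - 1))
    between = np.zeros(n)
    for si in range(n):
        for ti in range(n):
            if si >= ti or sigma[si, ti] == 0 or dist[si, ti] == INF:
                continue
            for vi in range(n):
                if vi in (si, ti):
                    continue
                if dist[si, vi] + dist[vi, ti] == dist[si, ti]:
                    between[vi] += sigma[si, vi] * sigma[vi, ti] / sigma[si, ti]
    if n > 2:
        between /= (n - 1) * (n - 2) / 2
    degree = np.array([G.degree(v) / (n - 1) for v in nodes])
    return nodes, closeness, between, degree


# ------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort (in memory) for integration tests."""
    cfg = CohortConfig(n_controls=5, n_patients=5, days=5, master_seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory, small_cohort):
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, out)
    return out


@pytest.fixture(scope="session")
def quick_run_config():
    """Classification settings scaled down for fast integration tests."""
    return RunConfig(runs=6, sgd_steps=800, repeats=6, master_seed=5)
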