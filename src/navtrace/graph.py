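"""Per-participant mobility graphs ("cognitive graphs") and their topology.

The whole trace is coarsened to grid cells; every occupied cell is a
node, every observed transition between consecutive samples an
undirected edge.  Cells dwelt in for less than a threshold (default
5 min, cumulative over the trace) are places crossed in transit: they
are removed, and each removed node's neighbours are pairwise
reconnected so that connectivity through transit corridors survives.
Node importance on the filtered graph is summarised by closeness,
betweenness and degree centrality on hop distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .grid import GridSpec, cell_indices
from .io import Bout, Trace, split_bouts
from .stats import make_histogram


@dataclass
class CentralityTable:
    """Per-node centralities of a mobility graph, each in [0, 1]."""

    nodes: list
    closeness: np.ndarray
    betweenness: np.ndarray
    degree: np.ndarray


def build_graph(
    trace: Trace,
    grid: GridSpec = GridSpec(),
    dwell_threshold: float = 300.0,
    bouts: list[Bout] | None = None,
) -> nx.Graph:
    """Build the mobility graph from a full trace.

    Dwell time per cell is accumulated from the inter-sample intervals,
    each interval split evenly between the cells of its two endpoint
    samples (which makes dwell, and hence the graph, invariant to
    reversing the trace's time direction).  Intervals spanning
    recording-bout gaps are unobserved time and are not attributed to
    any cell, and no edge is drawn across a gap.  Nodes below
    ``dwell_threshold`` are removed in ascending (dwell, cell) order,
    cliquing their current neighbours; self-loops and parallel edges
    are discarded.
    """
    if trace.xy is None:
        raise ValueError("project the trace before building the graph")
    if len(trace) == 0:
        raise ValueError("cannot build a graph from an empty trace")
    if bouts is None:
        bouts = split_bouts(trace)

    cells = cell_indices(trace.xy, grid)
    G = nx.Graph()
    dwell: dict[tuple, float] = {}
    for c in map(tuple, cells.tolist()):
        dwell.setdefault(c, 0.0)
    for bout in bouts:
        t = trace.time[bout.start : bout.end]
        cc = [tuple(c) for c in cells[bout.start : bout.end].tolist()]
        for k in range(len(cc) - 1):
            half = 0.5 * float(t[k + 1] - t[k])
            dwell[cc[k]] += half
            dwell[cc[k + 1]] += half
            if cc[k + 1] != cc[k]:
                G.add_edge(cc[k], cc[k + 1])
    G.add_nodes_from(dwell)
    nx.set_node_attributes(G, dwell, "dwell")

    doomed = sorted(
        (c for c, d in dwell.items() if d < dwell_threshold),
        key=lambda c: (dwell[c], c),
    )
    for c in doomed:
        neigh = list(G.neighbors(c))
        G.remove_node(c)
        for a_idx in range(len(neigh)):
            for b_idx in range(a_idx + 1, len(neigh)):
                G.add_edge(neigh[a_idx], neigh[b_idx])
    return G


def centralities(G: nx.Graph) -> CentralityTable:
    """Closeness, betweenness and degree centrality for every node.

    Closeness uses the component-scaled (Wasserman-Faust) formula so
    that disconnected graphs are handled gracefully; betweenness is the
    normalised shortest-path pass-through fraction; degree centrality is
    degree / (n - 1).
    """
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("centralities need at least two nodes")
    nodes = sorted(G.nodes)
    clo = nx.closeness_centrality(G, wf_improved=True)
    bet = nx.betweenness_centrality(G, normalized=True)
    deg = nx.degree_centrality(G)
    return CentralityTable(
        nodes=nodes,
        closeness=np.array([clo[v] for v in nodes]),
        betweenness=np.array([bet[v] for v in nodes]),
        degree=np.array([deg[v] for v in nodes]),
    )


def graph_feature_vector(
    G: nx.Graph,
    table: CentralityTable | None = None,
    bins: int = 10,
    min_nodes: int = 10,
) -> dict:
    """Participant-level graph features: node count + centrality histograms.

    Participants with fewer than ``min_nodes`` nodes carry too little
    topology and raise ``ValueError`` (callers exclude and log them).
    """
    n = G.number_of_nodes()
    if n < min_nodes:
        raise ValueError(f"graph has {n} nodes, below the minimum of {min_nodes}")
    if table is None:
        table = centralities(G)
    return {
        "node_count": float(n),
        "closeness": make_histogram(table.closeness, bins=bins, value_range=(0, 1)),
        "betweenness": make_histogram(table.betweenness, bins=bins, value_range=(0, 1)),
        "degree_centrality": make_histogram(table.degree, bins=bins, value_range=(0, 1)),
    }
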