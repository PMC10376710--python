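"""Natural visibility graphs and temporal communities for group signals.

Each (group, subgroup) median signal is turned into a natural visibility
graph on its timepoints: vertices are the present bins in time order, and
two vertices i < j are connected iff the straight line between
(t_i, y_i) and (t_j, y_j) passes strictly above every intermediate point,

    y_k < y_j + (y_i - y_j) * (t_j - t_k) / (t_j - t_i)   for all i < k < j.

Adjacent timepoints are always connected (the criterion is vacuous), so the
graph is connected.  The strict inequality means a constant series yields a
path graph and a strictly convex series the complete graph.

The temporal summary places community boundaries at the vertices of the
fewest-hops shortest path from the first to the last timepoint (ties broken
by the lexicographically smallest vertex sequence).  Walking through time,
an interior path vertex starts a new community when it shares strictly more
edges with the vertices ahead of it (up to the next boundary) than with the
community accumulated behind it; on a tie it stays with the earlier
community.  Communities are therefore always contiguous in time and cover
every vertex exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np


def _visible(values: np.ndarray, times: np.ndarray, i: int, j: int) -> bool:
    """Strict natural-visibility predicate for i < j."""
    yi, yj, ti, tj = values[i], values[j], times[i], times[j]
    for k in range(i + 1, j):
        if values[k] >= yj + (yi - yj) * (tj - times[k]) / (tj - ti):
            return False
    return True


def natural_visibility_graph(
    values: np.ndarray, times: np.ndarray | None = None
) -> nx.Graph:
    """Natural visibility graph of one series.

    NaN values are dropped; vertices are consecutive integers in time order
    with node attributes ``intensity`` (the series value) and ``time``.
    Requires at least two present points.
    """
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    times = np.asarray(times, dtype=float)
    present = ~np.isnan(values)
    values, times = values[present], times[present]
    n = len(values)
    if n < 2:
        raise ValueError("visibility graph needs at least 2 present points")
    g = nx.Graph()
    for v in range(n):
        g.add_node(v, intensity=float(values[v]), time=float(times[v]))
    for i in range(n - 1):
        g.add_edge(i, i + 1)
        for j in range(i + 2, n):
            if _visible(values, times, i, j):
                g.add_edge(i, j)
    return g


def lexicographic_shortest_path(g: nx.Graph, source: int, target: int) -> list[int]:
    """Fewest-hops path; among equally short paths, the lexicographically
    smallest vertex sequence.  Built from forward/backward BFS distances by
    always stepping to the smallest admissible neighbor."""
    d_from = nx.single_source_shortest_path_length(g, source)
    d_to = nx.single_source_shortest_path_length(g, target)
    total = d_from[target]
    path = [source]
    current = source
    while current != target:
        step = len(path) - 1
        candidates = [
            v for v in g.neighbors(current)
            if d_from.get(v) == step + 1 and d_to.get(v) == total - step - 1
        ]
        current = min(candidates)
        path.append(current)
    return path


@dataclass(frozen=True)
class TemporalCommunities:
    """Contiguous vertex communities plus the endpoint shortest path."""

    communities: tuple[tuple[int, ...], ...]
    shortest_path: tuple[int, ...]


def visibility_communities(g: nx.Graph) -> TemporalCommunities:
    """Partition timepoints into contiguous temporal communities."""
    n = g.number_of_nodes()
    if n == 1:
        return TemporalCommunities(((0,),), (0,))
    path = lexicographic_shortest_path(g, 0, n - 1)
    boundaries = sorted(set(path))
    interior = [b for b in boundaries if 0 < b < n - 1]
    next_boundary = {}
    for b in interior:
        later = [x for x in boundaries if x > b]
        next_boundary[b] = later[0] if later else n - 1
    communities: list[list[int]] = [[0]]
    for v in range(1, n):
        if v in next_boundary:
            behind = communities[-1]
            ahead = range(v + 1, next_boundary[v] + 1)
            edges_behind = sum(1 for u in behind if g.has_edge(v, u))
            edges_ahead = sum(1 for u in ahead if g.has_edge(v, u))
            if edges_ahead > edges_behind:
                communities.append([v])
                continue
        communities[-1].append(v)
    return TemporalCommunities(
        tuple(tuple(c) for c in communities), tuple(path)
    )


def median_group_signal(members: np.ndarray) -> np.ndarray:
    """Per-bin median across the member series, ignoring missing values.

    Bins missing in every member stay missing in the output.
    """
    members = np.atleast_2d(np.asarray(members, dtype=float))
    if members.size == 0:
        raise ValueError("median of an empty member set")
    out = np.full(members.shape[1], np.nan)
    present = ~np.isnan(members)
    for j in range(members.shape[1]):
        col = members[present[:, j], j]
        if col.size:
            out[j] = np.median(col)
    return out


def summarize_visibility(
    values: np.ndarray, times: np.ndarray | None = None
) -> dict:
    """JSON-ready visibility summary of one signal."""
    g = natural_visibility_graph(values, times)
    tc = visibility_communities(g)
    return {
        "vertices": [
            {"index": v, "time": g.nodes[v]["time"], "intensity": g.nodes[v]["intensity"]}
            for v in sorted(g.nodes)
        ],
        "edges": sorted([sorted(e) for e in g.edges]),
        "communities": [list(c) for c in tc.communities],
        "shortest_path": list(tc.shortest_path),
    }
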