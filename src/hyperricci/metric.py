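"""Directed shortest-path distances on a hypergraph.

The distance ``d(u, v)`` is the number of hyperedges on a shortest directed
path from ``u`` to ``v``: one step moves from any tail vertex of a hyperedge
to any head vertex of the same hyperedge.  Distances stay hop counts even in
weighted-measure mode — weights reshape the probability measures, not the
metric.  The "distinct vertices" clause of the path definition need not be
enforced: shortest walks and shortest paths coincide for hop counts.

The key geometric fact exploited by the curvature engine: if ``u`` supports
the mass of a hyperedge and ``v`` its hole, then ``d(u, v) <= 3`` (tail of an
incoming hyperedge -> tail -> head -> head of an outgoing hyperedge), so every
transport cost the engine needs is finite and at most 3.
"""

from __future__ import annotations

import math
from collections import deque
from typing import Iterable, Optional

import numpy as np

from .hypergraph import DirectedHypergraph

#: Sentinel for an unreachable target.
UNREACHABLE = math.inf


def _bfs_from(H: DirectedHypergraph, source: str, cap: Optional[int]) -> dict[str, int]:
    """Hop distances from ``source`` to every reachable vertex (<= cap)."""
    dist = {source: 0}
    frontier = deque([source])
    while frontier:
        u = frontier.popleft()
        du = dist[u]
        if cap is not None and du >= cap:
            continue
        for e in H.out_hyperedges(u):
            for v in e.head:
                if v not in dist:
                    dist[v] = du + 1
                    frontier.append(v)
    return dist


def shortest_path_length(
    H: DirectedHypergraph, u: str, v: str, cap: Optional[int] = None
) -> float:
    """Length of a shortest directed path from ``u`` to ``v``.

    Returns :data:`UNREACHABLE` (infinity) when no path exists, or when a
    ``cap`` is given and every path is longer than ``cap``.
    """
    H._require_vertex(u)
    H._require_vertex(v)
    if u == v:
        return 0
    dist = _bfs_from(H, u, cap)
    return dist.get(v, UNREACHABLE)


def support_distance_matrix(
    H: DirectedHypergraph,
    sources: Iterable[str],
    targets: Iterable[str],
    cap: Optional[int] = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Pairwise distance matrix between two vertex sets.

    Returns ``(D, src_order, dst_order)`` where ``D[i, j]`` is the distance
    from ``src_order[i]`` to ``dst_order[j]`` (infinity when unreachable).
    Vertex order is sorted for determinism.
    """
    src_order = sorted(set(sources))
    dst_order = sorted(set(targets))
    for vid in src_order + dst_order:
        H._require_vertex(vid)
    D = np.full((len(src_order), len(dst_order)), UNREACHABLE)
    for i, u in enumerate(src_order):
        dist = _bfs_from(H, u, cap)
        for j, v in enumerate(dst_order):
            if v in dist:
                D[i, j] = dist[v]
    return D, src_order, dst_order
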