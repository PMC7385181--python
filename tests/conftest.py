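"""Shared fixtures and independent transport oracles.

The oracles deliberately take different routes than the package's LP engine:

* :func:`exact_wasserstein` rescales the rational measures to integers and
  runs networkx's integer min-cost flow, giving an *exact* rational optimum;
* :func:`brute_force_wasserstein` exhaustively enumerates greedy extreme-point
  plans over every order of (source, target) pair choices — feasible for
  supports of a handful of vertices, and independent of any LP solver.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Callable

import networkx as nx
import pytest

from hyperricci import (
    DiscreteMeasure,
    FamilySpec,
    in_measure,
    make_family,
    out_measure,
    support_distance_matrix,
)


def dist_fn(H, mu_src: DiscreteMeasure, mu_dst: DiscreteMeasure) -> Callable[[str, str], float]:
    D, src, dst = support_distance_matrix(H, mu_src.support, mu_dst.support, cap=3)
    si = {u: i for i, u in enumerate(src)}
    ti = {v: j for j, v in enumerate(dst)}
    return lambda u, v: float(D[si[u], ti[v]])


def exact_wasserstein(
    mu_src: DiscreteMeasure, mu_dst: DiscreteMeasure, d: Callable[[str, str], float]
) -> Fraction:
    """Exact rational W via integer min-cost flow (networkx)."""
    a = {u: mu_src[u] for u in mu_src.support}
    b = {v: mu_dst[v] for v in mu_dst.support}
    scale = 1
    for mass in list(a.values()) + list(b.values()):
        scale = scale * mass.denominator // math.gcd(scale, mass.denominator)
    G = nx.DiGraph()
    for u, mass in a.items():
        G.add_node(("s", u), demand=-int(mass * scale))
    for v, mass in b.items():
        node = ("t", v)
        G.add_node(node, demand=G.nodes.get(node, {}).get("demand", 0) + int(mass * scale))
    for u in a:
        for v in b:
            cost = d(u, v)
            assert math.isfinite(cost) and float(cost).is_integer()
            G.add_edge(("s", u), ("t", v), weight=int(cost))
    flow = nx.min_cost_flow(G)
    return Fraction(nx.cost_of_flow(G, flow), scale)


def brute_force_wasserstein(
    mu_src: DiscreteMeasure, mu_dst: DiscreteMeasure, d: Callable[[str, str], float]
) -> Fraction:
    """Exhaustive enumeration of greedy extreme-point plans (tiny supports only)."""
    a0 = tuple(sorted((u, mu_src[u]) for u in mu_src.support))
    b0 = tuple(sorted((v, mu_dst[v]) for v in mu_dst.support))
    best: list[Fraction | None] = [None]

    def rec(a, b, cost: Fraction) -> None:
        active_a = [(i, u, s) for i, (u, s) in enumerate(a) if s > 0]
        active_b = [(j, v, t) for j, (v, t) in enumerate(b) if t > 0]
        if not active_a:
            if best[0] is None or cost < best[0]:
                best[0] = cost
            return
        if best[0] is not None and cost >= best[0]:
            return  # cannot improve: costs only grow
        for i, u, s in active_a:
            for j, v, t in active_b:
                move = min(s, t)
                a2 = a[:i] + ((u, s - move),) + a[i + 1 :]
                b2 = b[:j] + ((v, t - move),) + b[j + 1 :]
                rec(a2, b2, cost + move * Fraction(int(d(u, v))))

    rec(a0, b0, Fraction(0))
    assert best[0] is not None
    return best[0]


def random_spec(seed: int, n_vertices: int = 7, n_hyperedges: int = 5) -> FamilySpec:
    return FamilySpec(
        "random",
        seed=seed,
        n_vertices=n_vertices,
        n_hyperedges=n_hyperedges,
        tail_range=(1, 2),
        head_range=(1, 2),
    )


@pytest.fixture
def chain():
    """u -> x (e0), x -> y (e1), y -> v (e2): the minimal kappa = -2 witness."""
    from hyperricci import build_hypergraph

    return build_hypergraph([({"u"}, {"x"}), ({"x"}, {"y"}), ({"y"}, {"v"})])


@pytest.fixture
def two_shared_cycles():
    """Two directed 3-cycles sharing the edge x -> y."""
    return make_family(FamilySpec("weighted_counterexample", counter_weight=2.0))


def measures_and_dist(H, eid, weighted=False, policy="conserve"):
    mu_in = in_measure(H, eid, weighted=weighted, policy=policy)
    mu_out = out_measure(H, eid, weighted=weighted, policy=policy)
    return mu_in, mu_out, dist_fn(H, mu_in, mu_out)
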