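"""Seeded builders for hypergraph families of known curvature.

Each family realises a construction with a provable curvature profile —
constant curvature 1, 0 or -2, the hypertree closed form, directed cycles,
hyperloops — plus a seeded random family and the weighted counterexample
where two 3-cycles share an edge.  The generators are the synthetic-data
surface of the package: every theorem becomes testable at desk scale by
generating its family and certifying the prediction with the LP engine
(:func:`verify_family`).

All builders are deterministic given their spec (the random family given its
seed).
"""

from __future__ import annotations

import itertools
import random as _random
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .curvature import hyperedge_curvature, hypertree_closed_form
from .hypergraph import DirectedHypergraph, Hyperedge, Vertex

FAMILIES = (
    "ricci1_tripartite_digraph",
    "ricci1_tripartite_hyper",
    "flat_bipartite",
    "flat_tripartite",
    "negative_four_set",
    "hypertree",
    "directed_cycle",
    "hyperloop",
    "random",
    "weighted_counterexample",
)

#: Hyperedge id of the hyperedge whose curvature the hypertree closed form
#: (and the weighted counterexample) predicts.
DESIGNATED_ID = "designated"


@dataclass
class FamilySpec:
    """Parameters selecting one member of a generated family.

    ``sizes`` are the block sizes for the partitioned families; the hypertree
    takes ``(n, m, k, k_prime)``; the cycle takes ``cycle_k``; the random
    family takes vertex/hyperedge counts, tail/head size ranges and a seed.
    """

    family: str
    sizes: tuple[int, ...] = ()
    n: int = 1
    m: int = 1
    k: int = 0
    k_prime: int = 0
    cycle_k: int = 4
    seed: int = 0
    n_vertices: int = 8
    n_hyperedges: int = 5
    tail_range: tuple[int, int] = (1, 2)
    head_range: tuple[int, int] = (1, 2)
    counter_weight: float = 2.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if any(s < 1 for s in self.sizes):
            raise ValueError(f"sizes must be >= 1, got {self.sizes}")
        if self.family == "hypertree":
            if self.n < 1 or self.m < 1:
                raise ValueError(f"hypertree needs n, m >= 1, got n={self.n}, m={self.m}")
            if not 0 <= self.k <= self.n:
                raise ValueError(f"hypertree needs 0 <= k <= n, got k={self.k}, n={self.n}")
            if not 0 <= self.k_prime <= self.m:
                raise ValueError(
                    f"hypertree needs 0 <= k' <= m, got k'={self.k_prime}, m={self.m}"
                )
        if self.family == "directed_cycle" and self.cycle_k < 3:
            raise ValueError(f"directed cycle needs k >= 3, got {self.cycle_k}")


@dataclass
class FamilyReport:
    """Certification of a generated hypergraph against its family's theorem."""

    family: str
    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks.append((name, passed, detail))

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.checks)


def _block(prefix: str, size: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(size)]


def _sizes(spec: FamilySpec, count: int, default: int = 2) -> tuple[int, ...]:
    if not spec.sizes:
        return (default,) * count
    if len(spec.sizes) != count:
        raise ValueError(
            f"family {spec.family!r} needs {count} block sizes, got {spec.sizes}"
        )
    return spec.sizes


def _complete_block_edges(
    H: DirectedHypergraph, blocks: list[list[str]], arcs: list[tuple[int, int]]
) -> None:
    """Add every single directed edge between the given block pairs."""
    i = len(H.hyperedges)
    for a, b in arcs:
        for x in blocks[a]:
            for y in blocks[b]:
                H.add_hyperedge(Hyperedge(f"e{i}", frozenset({x}), frozenset({y})))
                i += 1


def make_family(spec: FamilySpec) -> DirectedHypergraph:
    """Build the hypergraph selected by ``spec``.  See module docstring."""
    fam = spec.family
    H = DirectedHypergraph()

    if fam in ("ricci1_tripartite_digraph", "ricci1_tripartite_hyper"):
        a, b, c = _sizes(spec, 3)
        blocks = [_block("a", a), _block("b", b), _block("c", c)]
        for blk in blocks:
            for v in blk:
                H.add_vertex(v)
        if fam == "ricci1_tripartite_digraph":
            _complete_block_edges(H, blocks, [(0, 1), (1, 2), (2, 0)])
        else:
            for i, (s, t) in enumerate([(0, 1), (1, 2), (2, 0)]):
                H.add_hyperedge(
                    Hyperedge(f"e{i}", frozenset(blocks[s]), frozenset(blocks[t]))
                )
        return H

    if fam == "flat_bipartite":
        a, b = _sizes(spec, 2, default=3)
        A, B = _block("src", a), _block("snk", b)
        for v in A + B:
            H.add_vertex(v)
        # one set-valued hyperedge covering both sides plus singleton spokes:
        # any source->sink collection is Ricci flat, this one is also connected
        H.add_hyperedge(Hyperedge("e0", frozenset(A), frozenset(B)))
        for i, x in enumerate(A):
            H.add_hyperedge(
                Hyperedge(f"e{i + 1}", frozenset({x}), frozenset({B[i % b]}))
            )
        return H

    if fam == "flat_tripartite":
        a, b, c = _sizes(spec, 3)
        blocks = [_block("a", a), _block("b", b), _block("c", c)]
        for blk in blocks:
            for v in blk:
                H.add_vertex(v)
        # source -> saddle, saddle -> sink, source -> sink
        _complete_block_edges(H, blocks, [(0, 1), (1, 2), (0, 2)])
        return H

    if fam == "negative_four_set":
        sizes = _sizes(spec, 4, default=1)
        blocks = [_block(p, s) for p, s in zip("abcd", sizes)]
        for blk in blocks:
            for v in blk:
                H.add_vertex(v)
        _complete_block_edges(H, blocks, [(0, 1), (1, 2), (2, 3), (3, 0)])
        return H

    if fam == "hypertree":
        n, m, k, kp = spec.n, spec.m, spec.k, spec.k_prime
        A, B = _block("x", n), _block("y", m)
        for v in A + B:
            H.add_vertex(v)
        H.add_hyperedge(Hyperedge(DESIGNATED_ID, frozenset(A), frozenset(B)))
        i = 0
        # the last n-k tail vertices get a fresh singleton feeder, so exactly
        # k tail vertices keep d_in = 0 (and dually on the head side)
        for x in A[k:]:
            f = f"f{i}"
            H.add_vertex(f)
            H.add_hyperedge(Hyperedge(f"feed{i}", frozenset({f}), frozenset({x})))
            i += 1
        j = 0
        for y in B[kp:]:
            g = f"g{j}"
            H.add_vertex(g)
            H.add_hyperedge(Hyperedge(f"drain{j}", frozenset({y}), frozenset({g})))
            j += 1
        return H

    if fam == "directed_cycle":
        k = spec.cycle_k
        V = _block("v", k)
        for v in V:
            H.add_vertex(v)
        for i in range(k):
            H.add_hyperedge(
                Hyperedge(f"e{i}", frozenset({V[i]}), frozenset({V[(i + 1) % k]}))
            )
        return H

    if fam == "hyperloop":
        (size,) = _sizes(spec, 1, default=3)
        V = frozenset(_block("x", size))
        for v in sorted(V):
            H.add_vertex(v)
        H.add_hyperedge(Hyperedge("e0", V, V))
        return H

    if fam == "random":
        return _random_hypergraph(spec)

    if fam == "weighted_counterexample":
        w = spec.counter_weight
        for v in ("x", "y", "z1", "z2"):
            H.add_vertex(v)
        H.add_hyperedge(Hyperedge(DESIGNATED_ID, frozenset({"x"}), frozenset({"y"})))
        H.add_hyperedge(Hyperedge("cyc1_out", frozenset({"y"}), frozenset({"z1"})))
        H.add_hyperedge(Hyperedge("cyc1_back", frozenset({"z1"}), frozenset({"x"}), 1.0))
        H.add_hyperedge(Hyperedge("cyc2_out", frozenset({"y"}), frozenset({"z2"})))
        H.add_hyperedge(Hyperedge("cyc2_back", frozenset({"z2"}), frozenset({"x"}), w))
        return H

    raise AssertionError(f"unhandled family {fam!r}")  # pragma: no cover


def _random_hypergraph(spec: FamilySpec, max_tries: int = 100) -> DirectedHypergraph:
    """Seeded random hypergraph, weakly connected by rejection sampling."""
    rng = _random.Random(spec.seed)
    nv, ne = spec.n_vertices, spec.n_hyperedges
    lo_t, hi_t = spec.tail_range
    lo_h, hi_h = spec.head_range
    if not (1 <= lo_t <= hi_t <= nv and 1 <= lo_h <= hi_h <= nv):
        raise ValueError("tail/head size ranges must lie within [1, n_vertices]")
    V = _block("v", nv)
    for _ in range(max_tries):
        H = DirectedHypergraph()
        for v in V:
            H.add_vertex(v)
        for i in range(ne):
            tail = frozenset(rng.sample(V, rng.randint(lo_t, hi_t)))
            head = frozenset(rng.sample(V, rng.randint(lo_h, hi_h)))
            H.add_hyperedge(Hyperedge(f"e{i}", tail, head))
        if H.validate().ok:
            return H
    raise RuntimeError(
        f"could not generate a weakly connected random hypergraph in {max_tries} "
        f"tries (n_vertices={nv}, n_hyperedges={ne}); use more hyperedges"
    )


def designated_hyperedge(H: DirectedHypergraph) -> str:
    """Id of the hyperedge whose curvature the family's formula predicts."""
    try:
        H.hyperedge(DESIGNATED_ID)
    except KeyError:
        raise ValueError(
            "this hypergraph has no designated hyperedge; it was not built from "
            "a hypertree or weighted_counterexample spec"
        ) from None
    return DESIGNATED_ID


def ricci1_digraph_gap_instance() -> DirectedHypergraph:
    """A Ricci-1 hypergraph whose corresponding digraph is *not* Ricci 1.

    Synthetic witness found by hand: the set-valued hyperedge ``{x1, x2} ->
    {y}`` pools the masses of the two tail vertices into a measure matching
    the head's pooled holes, while the single digraph edges ``x1 -> y`` and
    ``x2 -> y`` each see only half the picture and curve below 1.
    """
    H = DirectedHypergraph()
    for v in ("x1", "x2", "y", "u1", "u2"):
        H.add_vertex(v)
    H.add_hyperedge(Hyperedge("e", frozenset({"x1", "x2"}), frozenset({"y"})))
    H.add_hyperedge(Hyperedge("ey", frozenset({"y"}), frozenset({"u1", "u2"})))
    H.add_hyperedge(Hyperedge("eu1", frozenset({"u1"}), frozenset({"x1"})))
    H.add_hyperedge(Hyperedge("eu2", frozenset({"u2"}), frozenset({"x2"})))
    return H


def _vertex_multigraph(H: DirectedHypergraph) -> nx.MultiDiGraph:
    G = nx.MultiDiGraph()
    G.add_nodes_from(H.vertex_ids)
    for e in H.hyperedges:
        for x in e.tail:
            for y in e.head:
                G.add_edge(x, y, key=e.id)
    return G


def _count_directed_paths(H: DirectedHypergraph) -> dict[tuple[str, str], int]:
    """Number of directed paths between every ordered vertex pair.

    Only meaningful on acyclic hypergraphs (where walks and paths coincide);
    counts parallel hyperedges as distinct paths.
    """
    G = _vertex_multigraph(H)
    order = list(nx.topological_sort(nx.DiGraph(G)))
    counts: dict[tuple[str, str], int] = {}
    for src in order:
        paths = {src: 1}
        for u in order[order.index(src):]:
            if u not in paths:
                continue
            for _, v, _ in G.out_edges(u, keys=True):
                paths[v] = paths.get(v, 0) + paths[u]
        for v, c in paths.items():
            if v != src:
                counts[(src, v)] = c
    return counts


def is_hypertree(H: DirectedHypergraph) -> tuple[bool, str]:
    """Check the two hypertree conditions: unique directed paths, no cycles."""
    for e in H.hyperedges:
        if e.is_hyperloop():
            return False, f"hyperedge {e.id!r} is a hyperloop"
    G = nx.DiGraph(_vertex_multigraph(H))
    if not nx.is_directed_acyclic_graph(G):
        return False, "contains a directed cycle"
    for (u, v), c in _count_directed_paths(H).items():
        if c > 1:
            return False, f"{c} directed paths from {u!r} to {v!r}"
    return True, ""


def verify_family(H: DirectedHypergraph, spec: FamilySpec, tol: float = 1e-9) -> FamilyReport:
    """Recompute curvatures and certify the family's predicted values."""
    report = FamilyReport(spec.family)
    report.add("weakly_connected", H.validate().ok, H.validate().message())

    expected_constant = {
        "ricci1_tripartite_digraph": 1.0,
        "ricci1_tripartite_hyper": 1.0,
        "flat_bipartite": 0.0,
        "flat_tripartite": 0.0,
        "negative_four_set": -2.0,
        "hyperloop": 1.0,
    }

    if spec.family in expected_constant:
        want = expected_constant[spec.family]
        for e in H.hyperedges:
            r = hyperedge_curvature(H, e)
            report.add(
                f"kappa({e.id})={want:g}",
                abs(r.kappa - want) <= tol,
                f"got {r.kappa:.12g}",
            )
    elif spec.family == "hypertree":
        ok, why = is_hypertree(H)
        report.add("is_hypertree", ok, why)
        want = float(hypertree_closed_form(spec.n, spec.m, spec.k, spec.k_prime))
        r = hyperedge_curvature(H, designated_hyperedge(H))
        report.add(
            "designated_kappa_matches_closed_form",
            abs(r.kappa - want) <= tol,
            f"got {r.kappa:.12g}, want {want:.12g}",
        )
    elif spec.family == "directed_cycle":
        want = 1.0 if spec.cycle_k == 3 else -2.0
        for e in H.hyperedges:
            r = hyperedge_curvature(H, e)
            report.add(
                f"kappa({e.id})={want:g}",
                abs(r.kappa - want) <= tol,
                f"got {r.kappa:.12g}",
            )
    elif spec.family == "weighted_counterexample":
        r_unw = hyperedge_curvature(H, DESIGNATED_ID, weighted=False)
        report.add("unit_weights_kappa=1", abs(r_unw.kappa - 1.0) <= tol, f"got {r_unw.kappa:g}")
        r_w = hyperedge_curvature(H, DESIGNATED_ID, weighted=True)
        expect_break = spec.counter_weight != 1.0
        report.add(
            "unequal_weights_break_ricci1" if expect_break else "unit_weight_keeps_ricci1",
            (abs(r_w.kappa - 1.0) > tol) == expect_break,
            f"got weighted kappa {r_w.kappa:g}",
        )
    # "random" has no predicted value beyond connectivity
    return report
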