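"""Directed-hypergraph data model.

A directed hypergraph ``H = (V, E)`` is a vertex set together with a list of
hyperedges, each a directional relation from a non-empty tail set ``A_e`` to a
non-empty head set ``B_e``.  Directed graphs are the special case where every
tail and head is a singleton.  Chemical reaction networks are the motivating
example: a reaction transforms a set of educts (tail) into a set of products
(head), so a metabolic network is naturally a directed hypergraph.

Parallel hyperedges (identical tail and head) are permitted and are counted
with multiplicity by the degree functions, because the curvature measures
divide by in/out-degrees counted as numbers of hyperedges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence


@dataclass
class Vertex:
    """A vertex with an opaque text id and a positive weight.

    The weight is only consulted in weighted-measure mode; the default of 1
    makes the weighted definitions collapse to the unweighted ones.
    """

    id: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("vertex id must be a non-empty string")
        if self.weight <= 0:
            raise ValueError(f"vertex {self.id!r}: weight must be > 0, got {self.weight}")


@dataclass
class Hyperedge:
    """A directed hyperedge tail -> head with optional weights.

    ``incidence_weights`` optionally overrides vertex weights in the context of
    this hyperedge only (a vertex may carry different weights in the different
    hyperedges it participates in).
    """

    id: str
    tail: frozenset[str]
    head: frozenset[str]
    weight: float = 1.0
    incidence_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tail = frozenset(self.tail)
        self.head = frozenset(self.head)
        if not self.tail:
            raise ValueError(f"hyperedge {self.id!r}: empty tail set")
        if not self.head:
            raise ValueError(f"hyperedge {self.id!r}: empty head set")
        if self.weight <= 0:
            raise ValueError(f"hyperedge {self.id!r}: weight must be > 0, got {self.weight}")
        for v, w in self.incidence_weights.items():
            if w <= 0:
                raise ValueError(
                    f"hyperedge {self.id!r}: incidence weight of {v!r} must be > 0, got {w}"
                )

    @property
    def n(self) -> int:
        """Tail size |A_e|."""
        return len(self.tail)

    @property
    def m(self) -> int:
        """Head size |B_e|."""
        return len(self.head)

    def is_hyperloop(self) -> bool:
        """True when tail and head intersect."""
        return bool(self.tail & self.head)


@dataclass
class DegreeReport:
    vertex: str
    d_in: int
    d_out: int


@dataclass
class ValidationReport:
    """Outcome of :meth:`DirectedHypergraph.validate`."""

    weakly_connected: bool
    duplicate_vertex_ids: list[str]
    duplicate_hyperedge_ids: list[str]
    dangling_references: list[tuple[str, str]]  # (hyperedge id, vertex id)

    @property
    def ok(self) -> bool:
        return (
            self.weakly_connected
            and not self.duplicate_vertex_ids
            and not self.duplicate_hyperedge_ids
            and not self.dangling_references
        )

    def message(self) -> str:
        problems = []
        if not self.weakly_connected:
            problems.append("hypergraph is not weakly connected")
        if self.duplicate_vertex_ids:
            problems.append(f"duplicate vertex ids: {sorted(self.duplicate_vertex_ids)}")
        if self.duplicate_hyperedge_ids:
            problems.append(f"duplicate hyperedge ids: {sorted(self.duplicate_hyperedge_ids)}")
        if self.dangling_references:
            problems.append(f"dangling vertex references: {sorted(self.dangling_references)}")
        return "; ".join(problems) if problems else "ok"


class DirectedHypergraph:
    """A directed hypergraph with ordered hyperedges and opaque vertex ids.

    Weak connectivity is a *validation* gate, not a construction invariant, so
    that generators can assemble components before joining them.  Curvature
    computations require :meth:`validate` to pass.
    """

    def __init__(
        self,
        vertices: Iterable[Vertex] = (),
        hyperedges: Iterable[Hyperedge] = (),
    ) -> None:
        self._vertices: dict[str, Vertex] = {}
        self._hyperedges: list[Hyperedge] = []
        self._by_id: dict[str, Hyperedge] = {}
        # adjacency: vertex -> indices of hyperedges having it in tail / head
        self._out_index: dict[str, list[int]] = {}
        self._in_index: dict[str, list[int]] = {}
        for v in vertices:
            self.add_vertex(v)
        for e in hyperedges:
            self.add_hyperedge(e)

    # -- construction -------------------------------------------------------

    def add_vertex(self, v: Vertex | str) -> Vertex:
        if isinstance(v, str):
            v = Vertex(v)
        if v.id in self._vertices:
            raise ValueError(f"duplicate vertex id {v.id!r}")
        self._vertices[v.id] = v
        self._out_index.setdefault(v.id, [])
        self._in_index.setdefault(v.id, [])
        return v

    def add_hyperedge(self, e: Hyperedge) -> Hyperedge:
        if e.id in self._by_id:
            raise ValueError(f"duplicate hyperedge id {e.id!r}")
        for vid in e.tail | e.head:
            if vid not in self._vertices:
                raise ValueError(f"hyperedge {e.id!r} references unknown vertex {vid!r}")
        idx = len(self._hyperedges)
        self._hyperedges.append(e)
        self._by_id[e.id] = e
        for vid in e.tail:
            self._out_index[vid].append(idx)
        for vid in e.head:
            self._in_index[vid].append(idx)
        return e

    # -- inspection ---------------------------------------------------------

    @property
    def vertices(self) -> dict[str, Vertex]:
        return dict(self._vertices)

    @property
    def vertex_ids(self) -> list[str]:
        return list(self._vertices)

    @property
    def hyperedges(self) -> list[Hyperedge]:
        return list(self._hyperedges)

    def hyperedge(self, eid: str) -> Hyperedge:
        try:
            return self._by_id[eid]
        except KeyError:
            raise KeyError(f"unknown hyperedge id {eid!r}") from None

    def __contains__(self, vid: str) -> bool:
        return vid in self._vertices

    def __len__(self) -> int:
        return len(self._vertices)

    def _require_vertex(self, vid: str) -> None:
        if vid not in self._vertices:
            raise KeyError(f"unknown vertex id {vid!r}")

    def vertex_weight(self, vid: str) -> float:
        self._require_vertex(vid)
        return self._vertices[vid].weight

    def out_hyperedges(self, vid: str) -> list[Hyperedge]:
        """Hyperedges with ``vid`` in their tail, with multiplicity."""
        self._require_vertex(vid)
        return [self._hyperedges[i] for i in self._out_index[vid]]

    def in_hyperedges(self, vid: str) -> list[Hyperedge]:
        """Hyperedges with ``vid`` in their head, with multiplicity."""
        self._require_vertex(vid)
        return [self._hyperedges[i] for i in self._in_index[vid]]

    def degrees(self, vid: str) -> DegreeReport:
        """In/out degree of a vertex, counting hyperedges with multiplicity.

        ``d_in`` counts hyperedges whose head contains the vertex, ``d_out``
        those whose tail contains it; a hyperloop contributes to both.
        """
        self._require_vertex(vid)
        return DegreeReport(vid, len(self._in_index[vid]), len(self._out_index[vid]))

    # -- derived structures -------------------------------------------------

    def corresponding_digraph(self) -> "DirectedHypergraph":
        """The corresponding directed graph, as a hypergraph of singleton edges.

        Every hyperedge ``A -> B`` with |A| = n, |B| = m is replaced by its
        n*m tail-to-head directed edges.  Edges induced by distinct hyperedges
        are kept as parallel edges: merging them would change the degrees that
        the single-edge curvature of the digraph depends on.
        """
        out = DirectedHypergraph()
        for v in self._vertices.values():
            out.add_vertex(Vertex(v.id, v.weight))
        for e in self._hyperedges:
            for x in sorted(e.tail):
                for y in sorted(e.head):
                    out.add_hyperedge(
                        Hyperedge(f"{e.id}:{x}->{y}", frozenset({x}), frozenset({y}), e.weight)
                    )
        return out

    def validate(self) -> ValidationReport:
        """Check weak connectivity (and id hygiene, trivially true after
        construction).  Curvature operations require ``validate().ok``."""
        # weak connectivity: union-find over each hyperedge's member set
        parent: dict[str, str] = {v: v for v in self._vertices}

        def find(a: str) -> str:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a: str, b: str) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for e in self._hyperedges:
            members = sorted(e.tail | e.head)
            for other in members[1:]:
                union(members[0], other)
        roots = {find(v) for v in self._vertices}
        connected = len(roots) <= 1
        return ValidationReport(
            weakly_connected=connected,
            duplicate_vertex_ids=[],
            duplicate_hyperedge_ids=[],
            dangling_references=[],
        )

    def require_valid(self) -> None:
        report = self.validate()
        if not report.ok:
            raise ValueError(f"invalid hypergraph: {report.message()}")

    def __repr__(self) -> str:
        return (
            f"DirectedHypergraph(|V|={len(self._vertices)}, "
            f"|E|={len(self._hyperedges)})"
        )


def build_hypergraph(
    edge_specs: Sequence[
        tuple[Iterable[str], Iterable[str]]
        | tuple[Iterable[str], Iterable[str], Optional[float]]
        | tuple[Iterable[str], Iterable[str], Optional[float], Optional[Mapping[str, float]]]
    ],
    vertex_weights: Optional[Mapping[str, float]] = None,
) -> DirectedHypergraph:
    """Build a hypergraph from ``(tail, head[, weight[, incidence_weights]])`` tuples.

    The vertex set is the union of all endpoints (plus any ids mentioned in
    ``vertex_weights``); hyperedges keep input order and get stable ids
    ``e0, e1, ...``.
    """
    H = DirectedHypergraph()
    vertex_weights = dict(vertex_weights or {})
    seen: set[str] = set()
    norm: list[tuple[frozenset[str], frozenset[str], float, dict[str, float]]] = []
    for i, spec in enumerate(edge_specs):
        tail, head = frozenset(spec[0]), frozenset(spec[1])
        if not tail or not head:
            raise ValueError(f"edge spec #{i} ({spec!r}): tail and head must be non-empty")
        weight = 1.0
        if len(spec) >= 3 and spec[2] is not None:
            weight = float(spec[2])
        iw: dict[str, float] = {}
        if len(spec) >= 4 and spec[3] is not None:
            iw = dict(spec[3])
        norm.append((tail, head, weight, iw))
        seen |= tail | head
    for vid in sorted(seen | set(vertex_weights)):
        H.add_vertex(Vertex(vid, vertex_weights.get(vid, 1.0)))
    for i, (tail, head, weight, iw) in enumerate(norm):
        H.add_hyperedge(Hyperedge(f"e{i}", tail, head, weight, iw))
    return H


def degrees(H: DirectedHypergraph, vid: str) -> DegreeReport:
    """Module-level alias for :meth:`DirectedHypergraph.degrees`."""
    return H.degrees(vid)


def corresponding_digraph(H: DirectedHypergraph) -> DirectedHypergraph:
    """Module-level alias for :meth:`DirectedHypergraph.corresponding_digraph`."""
    return H.corresponding_digraph()


def validate(H: DirectedHypergraph) -> ValidationReport:
    """Module-level alias for :meth:`DirectedHypergraph.validate`."""
    return H.validate()
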