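"""The mass and hole measures of a directed hyperedge.

For a hyperedge ``e: A -> B`` with ``|A| = n`` and ``|B| = m``, curvature
compares two probability measures on the vertex set:

* the **mass** ``mu_A_in``: each tail vertex ``x_i`` owns ``1/n`` of the unit
  mass; if ``x_i`` has no incoming hyperedge the share stays at ``x_i``,
  otherwise each incoming hyperedge ``e'`` spreads the share uniformly over
  its tail ``A_{e'}``, contributing ``1/(n * d_in(x_i) * |A_{e'}|)`` to each
  tail vertex of ``e'``;
* the **hole** ``mu_B_out``: the mirror image over head vertices, out-degrees
  and the heads of outgoing hyperedges.

Weighted mode replaces each of the three uniform factors by its weighted
counterpart: vertex-weight share within ``A``, hyperedge-weight share among
the incoming hyperedges of ``x_i``, and vertex-weight share within
``A_{e'}`` (per-hyperedge incidence weights override vertex weights where
given).  Each factor reduces to the uniform one at unit weights.

Hyperloops need a policy.  Read verbatim, the defining cases assign 0 at
``z = x_i`` whenever ``d_in(x_i) != 0``, which silently destroys
normalisation when ``x_i`` lies in the tail of one of its own incoming
hyperedges (e.g. ``A = B``).  The default policy ``"conserve"`` retains that
diagonal contribution at ``x_i`` itself, keeping both measures probability
measures and yielding ``kappa = 1`` for a full hyperloop; ``"literal"``
drops it, exactly as printed.  The two policies coincide on hyperloop-free
hypergraphs.

All arithmetic is exact (:class:`fractions.Fraction`); floats appear only
when a measure is exported for the transport LP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal

from .hypergraph import DirectedHypergraph, Hyperedge

Policy = Literal["conserve", "literal"]

POLICIES = ("conserve", "literal")


@dataclass
class DiscreteMeasure:
    """A non-negative mass assignment over vertices, exact-rational valued."""

    masses: dict[str, Fraction]
    side: Literal["in", "out"]
    hyperedge_id: str
    policy: Policy = "conserve"

    def __getitem__(self, vid: str) -> Fraction:
        return self.masses.get(vid, Fraction(0))

    def total(self) -> Fraction:
        return sum(self.masses.values(), Fraction(0))

    @property
    def support(self) -> set[str]:
        return {v for v, mass in self.masses.items() if mass != 0}

    def as_floats(self) -> dict[str, float]:
        return {v: float(mass) for v, mass in self.masses.items() if mass != 0}

    def items(self):
        return self.masses.items()


def _check_policy(policy: str) -> None:
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")


def _effective_weight(H: DirectedHypergraph, e: Hyperedge, vid: str) -> Fraction:
    """Vertex weight in the context of hyperedge ``e`` (incidence override)."""
    if vid in e.incidence_weights:
        return Fraction(e.incidence_weights[vid])
    return Fraction(H.vertex_weight(vid))


def _measure(
    H: DirectedHypergraph,
    e: Hyperedge,
    side: Literal["in", "out"],
    weighted: bool,
    policy: Policy,
) -> DiscreteMeasure:
    _check_policy(policy)
    if side == "in":
        anchors = sorted(e.tail)
        neighbours = H.in_hyperedges
        spread_set = lambda ep: ep.tail  # noqa: E731 - tiny local accessor
    else:
        anchors = sorted(e.head)
        neighbours = H.out_hyperedges
        spread_set = lambda ep: ep.head  # noqa: E731

    masses: dict[str, Fraction] = {}

    def add(vid: str, amount: Fraction) -> None:
        if amount:
            masses[vid] = masses.get(vid, Fraction(0)) + amount

    if weighted:
        anchor_total = sum((_effective_weight(H, e, a) for a in anchors), Fraction(0))
    for a in anchors:
        if weighted:
            lead = _effective_weight(H, e, a) / anchor_total
        else:
            lead = Fraction(1, len(anchors))
        incident = neighbours(a)
        if not incident:
            add(a, lead)
            continue
        if weighted:
            degree_total = sum((Fraction(ep.weight) for ep in incident), Fraction(0))
        for ep in incident:
            if weighted:
                mid = Fraction(ep.weight) / degree_total
                spread_total = sum(
                    (_effective_weight(H, ep, z) for z in spread_set(ep)), Fraction(0)
                )
            else:
                mid = Fraction(1, len(incident))
            for z in sorted(spread_set(ep)):
                if weighted:
                    share = lead * mid * (_effective_weight(H, ep, z) / spread_total)
                else:
                    share = lead * mid * Fraction(1, len(spread_set(ep)))
                if z == a and policy == "literal":
                    continue  # the printed cases assign 0 on the diagonal
                add(z, share)
    return DiscreteMeasure(masses, side, e.id, policy)


def in_measure(
    H: DirectedHypergraph,
    e: Hyperedge | str,
    weighted: bool = False,
    policy: Policy = "conserve",
) -> DiscreteMeasure:
    """The mass measure ``mu_A_in`` of hyperedge ``e``."""
    if isinstance(e, str):
        e = H.hyperedge(e)
    return _measure(H, e, "in", weighted, policy)


def out_measure(
    H: DirectedHypergraph,
    e: Hyperedge | str,
    weighted: bool = False,
    policy: Policy = "conserve",
) -> DiscreteMeasure:
    """The hole measure ``mu_B_out`` of hyperedge ``e``."""
    if isinstance(e, str):
        e = H.hyperedge(e)
    return _measure(H, e, "out", weighted, policy)


def vertex_in_measure(
    H: DirectedHypergraph, x: str, weighted: bool = False, policy: Policy = "conserve"
) -> DiscreteMeasure:
    """Normalised single-vertex mass measure ``mu_x_in`` (the n = 1 case)."""
    return _measure(H, Hyperedge(f"vertex:{x}", frozenset({x}), frozenset({x})), "in", weighted, policy)


def vertex_out_measure(
    H: DirectedHypergraph, y: str, weighted: bool = False, policy: Policy = "conserve"
) -> DiscreteMeasure:
    """Normalised single-vertex hole measure ``mu_y_out`` (the m = 1 case)."""
    return _measure(H, Hyperedge(f"vertex:{y}", frozenset({y}), frozenset({y})), "out", weighted, policy)
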