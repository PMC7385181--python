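"""Reading and writing directed hypergraphs.

Two formats are supported:

* ``dhg`` — a plain-text hyperedge list, one hyperedge per line::

      tail_csv -> head_csv [; w=<positive real>]

  Vertex ids are non-empty tokens without commas, ``->`` or ``;``.  Blank
  lines and ``#`` comments are ignored.  Vertex weights and incidence weights
  cannot be expressed in this format.

* ``json`` — an object with ``vertices`` (id, optional weight) and
  ``hyperedges`` (id, tail, head, optional weight, optional incidence_weights).

``parse_hypergraph`` and ``serialize_hypergraph`` round-trip losslessly up to
whitespace; hyperedge order is preserved.
"""

from __future__ import annotations

import json as _json
import re

from .hypergraph import DirectedHypergraph, Hyperedge, Vertex

FORMATS = ("dhg", "json")

_WEIGHT_RE = re.compile(r"^w\s*=\s*(\S+)$")


class ParseError(ValueError):
    pass


def _parse_dhg(text: str) -> DirectedHypergraph:
    specs: list[tuple[frozenset[str], frozenset[str], float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" not in line:
            raise ParseError(f"line {lineno}: expected 'tail -> head', got {raw!r}")
        lhs, rhs = line.split("->", 1)
        weight = 1.0
        if ";" in rhs:
            rhs, opt = rhs.split(";", 1)
            m = _WEIGHT_RE.match(opt.strip())
            if not m:
                raise ParseError(f"line {lineno}: bad option {opt.strip()!r} (expected w=<real>)")
            try:
                weight = float(m.group(1))
            except ValueError:
                raise ParseError(f"line {lineno}: bad weight {m.group(1)!r}") from None
            if weight <= 0:
                raise ParseError(f"line {lineno}: weight must be > 0, got {weight}")
        tail = frozenset(t.strip() for t in lhs.split(",") if t.strip())
        head = frozenset(t.strip() for t in rhs.split(",") if t.strip())
        if not tail or not head:
            raise ParseError(f"line {lineno}: empty tail or head in {raw!r}")
        specs.append((tail, head, weight))
    H = DirectedHypergraph()
    vids = sorted({v for t, h, _ in specs for v in t | h})
    for vid in vids:
        H.add_vertex(Vertex(vid))
    for i, (tail, head, weight) in enumerate(specs):
        H.add_hyperedge(Hyperedge(f"e{i}", tail, head, weight))
    return H


def _serialize_dhg(H: DirectedHypergraph) -> str:
    lines = []
    for e in H.hyperedges:
        line = f"{','.join(sorted(e.tail))} -> {','.join(sorted(e.head))}"
        if e.weight != 1.0:
            line += f" ; w={e.weight:g}"
        lines.append(line)
    return "\n".join(lines) + "\n"


def _parse_json(text: str) -> DirectedHypergraph:
    try:
        doc = _json.loads(text)
    except _json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from None
    H = DirectedHypergraph()
    for v in doc.get("vertices", []):
        H.add_vertex(Vertex(v["id"], float(v.get("weight", 1.0))))
    for i, e in enumerate(doc.get("hyperedges", [])):
        eid = e.get("id", f"e{i}")
        tail, head = frozenset(e["tail"]), frozenset(e["head"])
        for vid in tail | head:
            if vid not in H:
                raise ParseError(
                    f"hyperedge {eid!r} references undeclared vertex {vid!r}"
                )
        H.add_hyperedge(
            Hyperedge(
                eid,
                tail,
                head,
                float(e.get("weight", 1.0)),
                {k: float(w) for k, w in e.get("incidence_weights", {}).items()},
            )
        )
    return H


def _serialize_json(H: DirectedHypergraph) -> str:
    doc = {
        "vertices": [
            {"id": v.id, **({"weight": v.weight} if v.weight != 1.0 else {})}
            for v in H.vertices.values()
        ],
        "hyperedges": [
            {
                "id": e.id,
                "tail": sorted(e.tail),
                "head": sorted(e.head),
                **({"weight": e.weight} if e.weight != 1.0 else {}),
                **(
                    {"incidence_weights": dict(e.incidence_weights)}
                    if e.incidence_weights
                    else {}
                ),
            }
            for e in H.hyperedges
        ],
    }
    return _json.dumps(doc, indent=1) + "\n"


def parse_hypergraph(text: str, fmt: str) -> DirectedHypergraph:
    """Parse a ``dhg`` or ``json`` document into a hypergraph."""
    if fmt == "dhg":
        return _parse_dhg(text)
    if fmt == "json":
        return _parse_json(text)
    raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def serialize_hypergraph(H: DirectedHypergraph, fmt: str) -> str:
    """Serialize a hypergraph to a ``dhg`` or ``json`` document."""
    if fmt == "dhg":
        return _serialize_dhg(H)
    if fmt == "json":
        return _serialize_json(H)
    raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
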