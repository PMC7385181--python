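"""Ollivier-Ricci curvature of directed hyperedges.

The curvature of a hyperedge ``e: A -> B`` is

    kappa(e) = 1 - W(mu_A_in, mu_B_out)

where ``W`` is the Wasserstein-1 (earth-mover) distance between the mass and
hole measures of :mod:`hyperricci.measures`, with directed hop distance as the
transport cost.  Because every mass vertex is within three hops of every hole
vertex, an optimal plan moves mass only over distances 0..3, and with
``mu_i`` the plan mass moved distance ``i``:

    sum_i mu_i = 1,   sum_i i * mu_i = W,   kappa = mu_0 - mu_2 - 2 * mu_3.

The decomposition ``(mu_0, .., mu_3)`` can differ between optimal plans but
the identities hold for all of them; the plan returned here is whichever
optimum the LP solver produced and is reported as non-canonical.

The transport problem is solved exactly as a dense transportation LP over the
two supports (a few dozen vertices at most) with scipy's HiGHS backend, and
the optimum is cross-checked against the solver's dual objective (strong
duality) at 1e-9.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Literal, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import linprog

from .hypergraph import DirectedHypergraph, Hyperedge
from .measures import (
    DiscreteMeasure,
    Policy,
    in_measure,
    out_measure,
    vertex_in_measure,
    vertex_out_measure,
)
from .metric import UNREACHABLE, shortest_path_length, support_distance_matrix

#: Absolute tolerance for the exact identities (Eq. totals, duality gap).
IDENTITY_TOL = 1e-9


class UnbalancedTransportError(ValueError):
    """Raised when the two measures have different total mass.

    Only reachable under the ``"literal"`` hyperloop policy, where the printed
    measure cases can destroy normalisation; curvature is undefined there.
    """


@dataclass
class TransportPlan:
    """An optimal coupling between the mass and the hole measures."""

    entries: dict[tuple[str, str], float]
    source: DiscreteMeasure
    target: DiscreteMeasure

    def mass(self, u: str, v: str) -> float:
        return self.entries.get((u, v), 0.0)

    def marginal_defect(self) -> float:
        """Largest deviation of the plan's marginals from the two measures."""
        row: dict[str, float] = {}
        col: dict[str, float] = {}
        for (u, v), mass in self.entries.items():
            row[u] = row.get(u, 0.0) + mass
            col[v] = col.get(v, 0.0) + mass
        defect = 0.0
        for u in set(row) | self.source.support:
            defect = max(defect, abs(row.get(u, 0.0) - float(self.source[u])))
        for v in set(col) | self.target.support:
            defect = max(defect, abs(col.get(v, 0.0) - float(self.target[v])))
        return defect


@dataclass
class CurvatureResult:
    """Curvature of one hyperedge with its transport diagnostics."""

    hyperedge_id: str
    n: int
    m: int
    W: float
    kappa: float
    mu: tuple[float, float, float, float]
    plan: TransportPlan

    @property
    def mu0(self) -> float:
        return self.mu[0]

    @property
    def mu1(self) -> float:
        return self.mu[1]

    @property
    def mu2(self) -> float:
        return self.mu[2]

    @property
    def mu3(self) -> float:
        return self.mu[3]


@dataclass
class PerturbationBound:
    """Allowed half-width for |kappa(e') - kappa(e)| under vertex changes."""

    mode: Literal["remove", "extend"]
    l: int
    l_prime: int
    bound: float


@dataclass
class TriangleEntry:
    """One directed triangle through the hyperedge, with its effect class."""

    u: str
    tail_vertex: str
    head_vertex: str
    kind: Literal["mu0_type", "mu2_tail_type", "mu2_head_type", "inert_type"]


@dataclass
class TriangleReport:
    hyperedge_id: str
    triangles: list[TriangleEntry]

    def count(self, kind: str) -> int:
        return sum(1 for t in self.triangles if t.kind == kind)


@dataclass
class PartitionResult:
    """Outcome of the Ricci-1 three-set partition search."""

    ok: bool
    sets: Optional[tuple[set[str], set[str], set[str]]]
    reason: str = ""


DistanceSpec = Union[
    Mapping[tuple[str, str], float],
    Callable[[str, str], float],
    tuple[np.ndarray, Sequence[str], Sequence[str]],
]


def _distance_lookup(dist: DistanceSpec) -> Callable[[str, str], float]:
    if callable(dist):
        return dist
    if isinstance(dist, tuple):
        D, src_order, dst_order = dist
        si = {u: i for i, u in enumerate(src_order)}
        ti = {v: j for j, v in enumerate(dst_order)}
        return lambda u, v: float(D[si[u], ti[v]])
    mapping = dist
    return lambda u, v: float(mapping[(u, v)])


def decomposition_identities(
    mu: Sequence[float],
) -> tuple[float, float, float]:
    """Total mass, Wasserstein cost and curvature implied by a decomposition.

    Given the fractions ``(mu_0, mu_1, mu_2, mu_3)`` of plan mass moved
    distance 0..3, returns ``(total, W, kappa)`` with ``W = mu_1 + 2 mu_2 +
    3 mu_3`` and ``kappa = mu_0 - mu_2 - 2 mu_3``.  For probability measures
    ``total`` is 1 and ``kappa = 1 - W``.
    """
    if len(mu) != 4:
        raise ValueError(f"expected 4 fractions (mu_0..mu_3), got {len(mu)}")
    mu0, mu1, mu2, mu3 = mu
    total = mu0 + mu1 + mu2 + mu3
    W = mu1 + 2 * mu2 + 3 * mu3
    kappa = mu0 - mu2 - 2 * mu3
    return total, W, kappa


def wasserstein_plan(
    mu_src: DiscreteMeasure,
    mu_dst: DiscreteMeasure,
    dist: DistanceSpec,
) -> tuple[float, TransportPlan]:
    """Exact Wasserstein-1 transport between two discrete measures.

    Solves the transportation LP over ``support(mu_src) x support(mu_dst)``
    with the given pairwise costs, verifies the optimum against the solver's
    dual objective (strong duality) within 1e-9, and returns the cost together
    with an optimal plan.  Negative solver round-off down to -1e-12 is clipped
    to zero and the marginals re-verified.
    """
    total_src, total_dst = mu_src.total(), mu_dst.total()
    if isinstance(total_src, Fraction) and isinstance(total_dst, Fraction):
        balanced = total_src == total_dst
    else:  # pragma: no cover - measures are always Fraction-valued here
        balanced = abs(float(total_src) - float(total_dst)) < 1e-12
    if not balanced:
        raise UnbalancedTransportError(
            f"total mass {float(total_src):.12g} != total hole {float(total_dst):.12g}; "
            "the transport problem has no coupling.  This can only happen under the "
            "'literal' hyperloop policy; use policy='conserve'."
        )

    src_order = sorted(mu_src.support)
    dst_order = sorted(mu_dst.support)
    d = _distance_lookup(dist)
    s, t = len(src_order), len(dst_order)
    if s == 0 and t == 0:
        empty = TransportPlan({}, mu_src, mu_dst)
        return 0.0, empty

    C = np.empty((s, t))
    for i, u in enumerate(src_order):
        for j, v in enumerate(dst_order):
            cij = d(u, v)
            if not math.isfinite(cij):
                raise ValueError(
                    f"infinite distance from {u!r} to {v!r}: the supports are not "
                    "mutually reachable (support bound violated)"
                )
            C[i, j] = cij

    a = np.array([float(mu_src[u]) for u in src_order])
    b = np.array([float(mu_dst[v]) for v in dst_order])

    # transportation LP: min C.x subject to row sums = a, column sums = b
    n_var = s * t
    A_eq = np.zeros((s + t, n_var))
    for i in range(s):
        A_eq[i, i * t : (i + 1) * t] = 1.0
    for j in range(t):
        A_eq[s + j, j::t] = 1.0
    b_eq = np.concatenate([a, b])
    res = linprog(C.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if res.status != 0:  # pragma: no cover - balanced problems are feasible
        raise RuntimeError(f"transport LP failed: {res.message}")

    X = res.x.reshape(s, t)
    if X.min() < -1e-12:  # pragma: no cover - HiGHS respects bounds
        raise RuntimeError(f"solver produced negative mass {X.min():.3e}")
    X = np.clip(X, 0.0, None)
    W = float((C * X).sum())

    # strong-duality certificate from the equality-constraint marginals
    duals = np.asarray(res.eqlin.marginals)
    dual_obj = float(b_eq @ duals)
    if abs(W - dual_obj) > IDENTITY_TOL:  # pragma: no cover - exact LP solve
        raise RuntimeError(
            f"duality gap {abs(W - dual_obj):.3e} exceeds {IDENTITY_TOL}"
        )

    entries = {
        (src_order[i], dst_order[j]): float(X[i, j])
        for i in range(s)
        for j in range(t)
        if X[i, j] > 0.0
    }
    plan = TransportPlan(entries, mu_src, mu_dst)
    if plan.marginal_defect() > 1e-9:  # pragma: no cover
        raise RuntimeError("transport plan violates its marginal constraints")
    return W, plan


def _decompose(plan: TransportPlan, d: Callable[[str, str], float]) -> tuple[float, ...]:
    mu = [0.0, 0.0, 0.0, 0.0]
    for (u, v), mass in plan.entries.items():
        k = int(round(d(u, v)))
        if not 0 <= k <= 3:  # pragma: no cover - support bound enforced upstream
            raise RuntimeError(f"transport distance {k} outside 0..3 for ({u!r}, {v!r})")
        mu[k] += mass
    return tuple(mu)


def hyperedge_curvature(
    H: DirectedHypergraph,
    e: Hyperedge | str,
    weighted: bool = False,
    policy: Policy = "conserve",
) -> CurvatureResult:
    """Curvature ``kappa(e) = 1 - W`` of one hyperedge, with diagnostics.

    Builds the mass and hole measures, the capped distance matrix between
    their supports (every entry must be <= 3; anything else is an internal
    error), solves the transport LP exactly, and decomposes the optimal plan
    into the fractions moved distance 0..3.  The identities ``sum mu_i =
    total``, ``sum i*mu_i = W`` and (for probability measures) ``kappa =
    mu_0 - mu_2 - 2 mu_3`` are asserted within 1e-9 before returning.
    """
    if isinstance(e, str):
        e = H.hyperedge(e)
    H.require_valid()
    mu_in = in_measure(H, e, weighted=weighted, policy=policy)
    mu_out = out_measure(H, e, weighted=weighted, policy=policy)

    D, src_order, dst_order = support_distance_matrix(
        H, mu_in.support, mu_out.support, cap=3
    )
    if not np.all(np.isfinite(D)):  # pragma: no cover - guaranteed by construction
        raise RuntimeError(
            f"support distance bound violated for hyperedge {e.id!r}: some mass "
            "vertex cannot reach some hole vertex within 3 hops"
        )
    dist = (D, src_order, dst_order)
    W, plan = wasserstein_plan(mu_in, mu_out, dist)
    kappa = 1.0 - W
    mu = _decompose(plan, _distance_lookup(dist))

    total = float(mu_in.total())
    checked_total, checked_W, checked_kappa = decomposition_identities(mu)
    if abs(checked_total - total) > IDENTITY_TOL:  # pragma: no cover
        raise RuntimeError("mu decomposition does not sum to the plan mass")
    if abs(checked_W - W) > IDENTITY_TOL:  # pragma: no cover
        raise RuntimeError("mu decomposition does not reproduce W")
    if abs(total - 1.0) <= IDENTITY_TOL and abs(checked_kappa - kappa) > IDENTITY_TOL:
        raise RuntimeError(  # pragma: no cover
            "kappa identity mu0 - mu2 - 2*mu3 violated by the optimal plan"
        )
    return CurvatureResult(e.id, e.n, e.m, W, kappa, mu, plan)


def curvature_spectrum(
    H: DirectedHypergraph,
    weighted: bool = False,
    policy: Policy = "conserve",
) -> list[CurvatureResult]:
    """Curvature of every hyperedge, in input order."""
    H.require_valid()
    return [hyperedge_curvature(H, e, weighted, policy) for e in H.hyperedges]


def spectrum_table(H: DirectedHypergraph, results: Sequence[CurvatureResult]):
    """Tabulate curvature results as a pandas DataFrame (one row per hyperedge)."""
    import pandas as pd

    rows = []
    for r in results:
        e = H.hyperedge(r.hyperedge_id)
        rows.append(
            {
                "hyperedge_id": r.hyperedge_id,
                "tail": ",".join(sorted(e.tail)),
                "head": ",".join(sorted(e.head)),
                "n": r.n,
                "m": r.m,
                "W": r.W,
                "kappa": r.kappa,
                "mu0": r.mu0,
                "mu1": r.mu1,
                "mu2": r.mu2,
                "mu3": r.mu3,
            }
        )
    return pd.DataFrame(rows)


def single_edge_curvature(
    H: DirectedHypergraph,
    x: str,
    y: str,
    weighted: bool = False,
    policy: Policy = "conserve",
) -> CurvatureResult:
    """Curvature of the single directed edge ``x -> y`` induced inside ``H``.

    This is the n = m = 1 case of the engine evaluated with the hypergraph's
    own incoming/outgoing structure and distances: the mass is the normalised
    single-vertex measure ``mu_x_in`` of ``H``, the hole ``mu_y_out``.  These
    are the per-edge curvatures whose minimum lower-bounds ``kappa(e)`` (an
    averaged coupling of their optimal plans is feasible for the hyperedge).
    """
    for vid in (x, y):
        H._require_vertex(vid)
    mu_in = vertex_in_measure(H, x, weighted, policy)
    mu_out = vertex_out_measure(H, y, weighted, policy)
    D, src_order, dst_order = support_distance_matrix(
        H, mu_in.support, mu_out.support, cap=3
    )
    dist = (D, src_order, dst_order)
    W, plan = wasserstein_plan(mu_in, mu_out, dist)
    mu = _decompose(plan, _distance_lookup(dist))
    return CurvatureResult(f"edge:{x}->{y}", 1, 1, W, 1.0 - W, mu, plan)


def curvature_bounds(
    H: DirectedHypergraph, e: Hyperedge | str
) -> tuple[float, float]:
    """Lower and upper bounds sandwiching ``kappa(e)``.

    * lower: the minimum of :func:`single_edge_curvature` over the n*m
      tail-to-head vertex pairs of ``e``;
    * upper: the overlap ``sum_u min(mu_A_in(u), mu_B_out(u))`` — only mass
      already sitting on a hole can avoid being moved.
    """
    if isinstance(e, str):
        e = H.hyperedge(e)
    H.require_valid()
    lower = math.inf
    for x in sorted(e.tail):
        for y in sorted(e.head):
            lower = min(lower, single_edge_curvature(H, x, y).kappa)
    mu_in = in_measure(H, e)
    mu_out = out_measure(H, e)
    upper = float(
        sum(
            (min(mu_in[u], mu_out[u]) for u in mu_in.support | mu_out.support),
            Fraction(0),
        )
    )
    return lower, upper


def dual_objective(
    f: Mapping[str, float],
    mu_src: DiscreteMeasure,
    mu_dst: DiscreteMeasure,
    dist: DistanceSpec,
) -> float:
    """Objective of a Lipschitz test function, a certified lower bound on W.

    ``f`` must satisfy ``f(u) - f(v) <= d(u, v)`` for every ``u`` in the
    source support and ``v`` in the target support; then
    ``sum f*mu_src - sum f*mu_dst <= W``.
    """
    d = _distance_lookup(dist)
    for u in sorted(mu_src.support):
        for v in sorted(mu_dst.support):
            duv = d(u, v)
            if math.isfinite(duv) and f[u] - f[v] > duv + 1e-12:
                raise ValueError(
                    f"f is not Lipschitz: f({u!r}) - f({v!r}) = "
                    f"{f[u] - f[v]:g} > d = {duv:g}"
                )
    value = sum(f[u] * float(mu_src[u]) for u in mu_src.support)
    value -= sum(f[v] * float(mu_dst[v]) for v in mu_dst.support)
    return value


def lipschitz_dual_optimum(
    H: DirectedHypergraph,
    e: Hyperedge | str,
    weighted: bool = False,
    policy: Policy = "conserve",
) -> float:
    """Supremum of the single-potential dual over Lipschitz functions.

    Maximises ``sum f*mu_A_in - sum f*mu_B_out`` over functions on the union
    of the two supports with ``f(u) - f(v) <= d(u, v)`` for every ordered
    pair at finite distance (a small LP).  Always <= W; equality holds when
    distances are symmetric, e.g. when every hyperedge has a reverse.
    """
    if isinstance(e, str):
        e = H.hyperedge(e)
    mu_in = in_measure(H, e, weighted=weighted, policy=policy)
    mu_out = out_measure(H, e, weighted=weighted, policy=policy)
    verts = sorted(mu_in.support | mu_out.support)
    idx = {v: i for i, v in enumerate(verts)}
    c = np.zeros(len(verts))
    for u in mu_in.support:
        c[idx[u]] -= float(mu_in[u])  # linprog minimises; negate to maximise
    for v in mu_out.support:
        c[idx[v]] += float(mu_out[v])
    rows, rhs = [], []
    for u, v in itertools.permutations(verts, 2):
        duv = shortest_path_length(H, u, v)
        if math.isfinite(duv):
            row = np.zeros(len(verts))
            row[idx[u]] = 1.0
            row[idx[v]] = -1.0
            rows.append(row)
            rhs.append(duv)
    res = linprog(
        c,
        A_ub=np.array(rows) if rows else None,
        b_ub=np.array(rhs) if rhs else None,
        bounds=(-100, 100),  # objective is shift-invariant; any box this wide is inert
        method="highs",
    )
    if res.status != 0:  # pragma: no cover
        raise RuntimeError(f"dual LP failed: {res.message}")
    return -float(res.fun)


def hypertree_closed_form(n: int, m: int, k: int, k_prime: int) -> Fraction:
    """Curvature of a hypertree hyperedge: ``-2 + k/n + k'/m``.

    ``n, m`` are tail/head sizes; ``k`` counts tail vertices with no incoming
    hyperedge and ``k'`` head vertices with no outgoing one.
    """
    if n < 1 or m < 1:
        raise ValueError(f"need n, m >= 1, got n={n}, m={m}")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 <= k_prime <= m:
        raise ValueError(f"need 0 <= k' <= m, got k'={k_prime}, m={m}")
    return Fraction(-2) + Fraction(k, n) + Fraction(k_prime, m)


def perturbation_bound(
    e_before: CurvatureResult,
    mode: Literal["remove", "extend"],
    l: int,
    l_prime: int,
) -> PerturbationBound:
    """Bound on the curvature change from removing/adding tail/head vertices.

    Removing ``l`` tail and ``l'`` head vertices from an (n, m) hyperedge:
    ``|kappa' - kappa| <= min(3 (l/n + l'/m), 3)``.  Extending by ``l, l'``
    vertices: ``|kappa' - kappa| <= min(3 (l/(l+n) + l'/(l'+m)), 3)``.
    """
    if l < 0 or l_prime < 0:
        raise ValueError("l and l' must be non-negative")
    n, m = e_before.n, e_before.m
    if mode == "remove":
        if l >= n or l_prime >= m:
            raise ValueError(
                f"removal would empty the tail or head (l={l} of n={n}, "
                f"l'={l_prime} of m={m})"
            )
        bound = min(3.0 * (l / n + l_prime / m), 3.0)
    elif mode == "extend":
        bound = min(3.0 * (l / (l + n) + l_prime / (l_prime + m)), 3.0)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'remove' or 'extend'")
    return PerturbationBound(mode, l, l_prime, bound)


def _edge_relation(H: DirectedHypergraph) -> set[tuple[str, str]]:
    """All tail-to-head vertex pairs induced by some hyperedge."""
    rel: set[tuple[str, str]] = set()
    for e in H.hyperedges:
        for x in e.tail:
            for y in e.head:
                rel.add((x, y))
    return rel


def classify_directed_triangles(
    H: DirectedHypergraph, e: Hyperedge | str
) -> TriangleReport:
    """Classify the directed triangles through a hyperedge by their curvature role.

    For each ``x_i`` in the tail, ``y_j`` in the head (linked by ``e``) and a
    third vertex ``u``, the triangle bounded by the pair of edges touching
    ``u`` falls in one of four classes:

    * ``mu0_type``: ``u -> x_i`` and ``y_j -> u`` — a directed 3-cycle; mass
      coincides with a hole at ``u`` and need not move, raising curvature;
    * ``mu2_tail_type``: ``x_i -> u`` and ``y_j -> u``;
    * ``mu2_head_type``: ``u -> x_i`` and ``u -> y_j`` — both can shorten
      transports to distance 2;
    * ``inert_type``: ``x_i -> u`` and ``u -> y_j`` — no effect on any mu_i.
    """
    if isinstance(e, str):
        e = H.hyperedge(e)
    rel = _edge_relation(H)
    triangles: list[TriangleEntry] = []
    for x in sorted(e.tail):
        for y in sorted(e.head):
            if x == y:
                continue
            for u in sorted(H.vertex_ids):
                if u in (x, y):
                    continue
                into_x, from_x = (u, x) in rel, (x, u) in rel
                into_y, from_y = (u, y) in rel, (y, u) in rel
                if into_x and from_y:
                    triangles.append(TriangleEntry(u, x, y, "mu0_type"))
                if from_x and from_y:
                    triangles.append(TriangleEntry(u, x, y, "mu2_tail_type"))
                if into_x and into_y:
                    triangles.append(TriangleEntry(u, x, y, "mu2_head_type"))
                if from_x and into_y:
                    triangles.append(TriangleEntry(u, x, y, "inert_type"))
    return TriangleReport(e.id, triangles)


def ricci_one_partition(H: DirectedHypergraph) -> PartitionResult:
    """Three-set cyclic partition ``A -> B -> C -> A`` of a Ricci-1 hypergraph.

    For a loopless, weakly connected hypergraph with every-hyperedge curvature
    1 and no reverse hyperedges, the vertex set splits into three sets with
    every tail inside one set and its head inside the cyclic successor.  The
    search grows the three sets from an arbitrary starting hyperedge by label
    propagation (the fixed-point closure of the constructive argument), capped
    at |V| rounds; any precondition failure, label conflict or non-convergence
    yields a failure report rather than an exception.
    """
    if not H.hyperedges:
        return PartitionResult(False, None, "no hyperedges")
    report = H.validate()
    if not report.ok:
        return PartitionResult(False, None, report.message())
    for e in H.hyperedges:
        if e.is_hyperloop():
            return PartitionResult(False, None, f"hyperedge {e.id!r} is a hyperloop")
    pairs = {(e.tail, e.head) for e in H.hyperedges}
    for tail, head in pairs:
        if (head, tail) in pairs:
            return PartitionResult(False, None, "a hyperedge has a reverse hyperedge")
    for e in H.hyperedges:
        r = hyperedge_curvature(H, e)
        if abs(r.kappa - 1.0) > IDENTITY_TOL:
            return PartitionResult(
                False, None, f"hyperedge {e.id!r} has kappa = {r.kappa:g} != 1"
            )

    labels: dict[str, int] = {}
    first = H.hyperedges[0]
    for v in first.tail:
        labels[v] = 0
    for v in first.head:
        labels[v] = 1

    def assign(v: str, lab: int) -> bool:
        if v in labels:
            return labels[v] == lab % 3
        labels[v] = lab % 3
        return True

    for _ in range(max(1, len(H))):
        changed = False
        for e in H.hyperedges:
            known = {labels[v] for v in e.tail if v in labels}
            known |= {(labels[v] - 1) % 3 for v in e.head if v in labels}
            if len(known) > 1:
                return PartitionResult(False, None, f"label conflict at {e.id!r}")
            if not known:
                continue
            lab = known.pop()
            for v in e.tail:
                if v not in labels:
                    changed = True
                if not assign(v, lab):
                    return PartitionResult(False, None, f"label conflict at {e.id!r}")
            for v in e.head:
                if v not in labels:
                    changed = True
                if not assign(v, lab + 1):
                    return PartitionResult(False, None, f"label conflict at {e.id!r}")
        if not changed:
            break
    else:
        return PartitionResult(False, None, "closure did not converge")

    if set(labels) != set(H.vertex_ids):
        return PartitionResult(False, None, "some vertices were never reached")
    sets = tuple({v for v, lab in labels.items() if lab == i} for i in range(3))
    for e in H.hyperedges:  # final explicit certification of the partition
        tl = {labels[v] for v in e.tail}
        hl = {labels[v] for v in e.head}
        if len(tl) != 1 or len(hl) != 1 or (tl.pop() + 1) % 3 != hl.pop():
            return PartitionResult(False, None, f"partition violated by {e.id!r}")
    return PartitionResult(True, sets, "")
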