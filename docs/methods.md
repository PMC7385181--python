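# Methods

## Model

A directed hypergraph `H = (V, E)` carries hyperedges `e: A_e → B_e` with
non-empty tail and head sets. The in-degree `d_in(x)` counts hyperedges with
`x` in their head, the out-degree `d_out(x)` those with `x` in their tail;
parallel hyperedges are allowed and counted with multiplicity, because the
measure construction divides shares by these counts. Weak connectivity of
the underlying undirected hypergraph is required before any curvature is
computed; it is a validation gate rather than a construction invariant so
that generators can assemble components before joining them.

The distance `d(u, v)` is the number of hyperedges on a shortest directed
path: one step moves from any tail vertex of a hyperedge to any head vertex
of the same hyperedge. Distances are hop counts even in weighted mode —
weights reshape the measures, not the metric. Shortest walks and shortest
paths coincide for hop counts, so the breadth-first search does not need to
enforce vertex distinctness.

For a hyperedge `e: A → B` the mass measure `μ_A^in` gives each tail vertex
`x_i` the share `1/n`; if `d_in(x_i) = 0` the share stays at `x_i`,
otherwise each incoming hyperedge `e′` spreads it uniformly over its tail,
contributing `1/(n · d_in(x_i) · |A_{e′}|)` per tail vertex of `e′`. The
hole measure `μ_B^out` mirrors this over heads and outgoing hyperedges. The
curvature is `κ(e) = 1 − W(μ_A^in, μ_B^out)` with `W` the Wasserstein-1
distance under `d`. Because the mass support lies one hop upstream of `A`
and the hole support one hop downstream of `B`, every transport distance is
at most 3, all costs are finite, and the decomposition `μ_0..μ_3` of an
optimal plan by distance moved satisfies `Σ μ_i = 1`, `Σ i·μ_i = W` and
`κ = μ_0 − μ_2 − 2μ_3 ∈ [−2, 1]`. The `μ_i` themselves may differ between
optimal plans; the identities do not, so the reported plan is explicitly
non-canonical.

## Hyperloop policy

Read verbatim, the defining cases of the measures put mass 0 at `z = x_i`
whenever `d_in(x_i) ≠ 0`. When `x_i` lies in the tail of one of its own
incoming hyperedges (any hyperedge with intersecting tail and head can
create this), the dropped diagonal contribution destroys normalisation, and
the two measures can end up with different totals — then no coupling
exists. The default policy `conserve` retains the diagonal contribution at
`x_i` itself: both measures stay probability measures, the full hyperloop
`A = B` gets `κ = 1` as the theory requires, and on hyperloop-free inputs
the policy coincides with the verbatim reading. The policy `literal`
implements the printed cases exactly and *refuses* the transport (a typed
error, exit code 3 in the CLI) when the totals differ.

## Weighted measures

In weighted mode each uniform factor is replaced by its weighted
counterpart, chosen so that every factor reduces to the uniform one at unit
weights:

* the leading `1/n` becomes `w_{x_i} / Σ_{x_j ∈ A} w_{x_j}`;
* the degree factor `1/d_in(x_i)` becomes `w_{e′}` over the total weight of
  the incoming hyperedges of `x_i` (the per-vertex reading of the
  summation; the alternative set-level reading does not degenerate to
  `1/d_in`);
* the spread factor `1/|A_{e′}|` becomes `w_z / Σ_{z′ ∈ A_{e′}} w_{z′}`,
  where per-hyperedge incidence weights override global vertex weights when
  given.

The classic failure of Ricci-1 rigidity under weights — two directed
3-cycles sharing an edge, with unequal weights on the two return edges —
is generated by the `weighted_counterexample` family and certified by the
engine: `κ(shared) = 1` at unit weights, `κ ≠ 1` otherwise.

## Transport solver

Supports never exceed a few dozen vertices, so the transport problem is
solved as a dense transportation LP (scipy `linprog`, HiGHS) over
`supp(μ_A^in) × supp(μ_B^out)` rather than by entropic approximation — the
identities above are asserted at 1e-9 absolute and demand exact optima.
Each solve is certified by strong duality against the solver's
equality-constraint marginals; negative round-off down to −1e-12 is clipped
and the marginals re-verified at 1e-9. Measures themselves are computed in
exact rational arithmetic (`fractions.Fraction`), which keeps totals exact
and lets the test suite compare the LP against an exact rational
min-cost-flow oracle.

## Bounds and diagnostics

* Lower bound: the minimum of the single-edge curvatures over the `n·m`
  tail-to-head vertex pairs, where each single edge `x → y` is evaluated as
  the `n = m = 1` case of the same engine *inside the original hypergraph*
  (normalised `μ_x^in` vs `μ_y^out`). Averaging the per-pair optimal plans
  yields a feasible coupling for `e`, which is what makes the minimum a
  bound. Re-deriving the per-edge measures inside the corresponding digraph
  instead changes degrees and shares and is not a valid bound; the package
  deliberately uses the in-hypergraph evaluation. The maximum over the same
  edges is *not* an upper bound — a shipped witness has `κ(e) = 1` with
  both induced edges at `−1/2`.
* Upper bound: the overlap `Σ_u min(μ_A^in(u), μ_B^out(u))`.
* Dual certificates: any function with `f(u) − f(v) ≤ d(u, v)` on support
  pairs certifies `Σ f·μ_A^in − Σ f·μ_B^out ≤ W`; the supremum over such
  potentials (a small LP) equals `W` when distances are symmetric, e.g.
  when every hyperedge has a reverse.
* Perturbation bounds: removing `(l, l′)` tail/head vertices changes `κ` by
  at most `min(3(l/n + l′/m), 3)`; extending by `(l, l′)` by at most
  `min(3(l/(l+n) + l′/(l′+m)), 3)`.
* Triangle classifier: directed triangles through a hyperedge are typed by
  which transport fraction they can affect (`μ_0` for 3-cycles through mass
  and hole, two `μ_2` types, and an inert type with no effect).
* Ricci-1 partition: for a loopless, reverse-free hypergraph with all
  `κ = 1`, label propagation from an arbitrary starting hyperedge grows the
  three sets of the cyclic partition `A → B → C → A`, capped at `|V|`
  rounds; conflicts, non-convergence or failed preconditions return a
  failure report rather than raising, since the converse of the partition
  property is false (a shipped counterexample has the partition but not
  constant curvature 1).

## Generators

The generated families are minimal witnesses of each constant-curvature
construction, not models of empirical networks:

* `ricci1_tripartite_digraph` / `ricci1_tripartite_hyper` — complete cyclic
  connections `A → B → C → A` as single edges / as three set-valued
  hyperedges (all `κ = 1`);
* `flat_bipartite` — sources to sinks only (all `κ = 0`); built as one
  covering set-valued hyperedge plus singleton spokes so the instance is
  weakly connected whatever the sizes;
* `flat_tripartite` — complete source/saddle/sink connections `A → B`,
  `B → C`, `A → C` (all `κ = 0`);
* `negative_four_set` — complete cyclic connections `A → B → C → D → A`
  (all `κ = −2`: every transport is forced to distance 3);
* `hypertree` — a designated `(n, m)` hyperedge with fresh singleton
  feeders on the `n − k` tail vertices that must have incoming hyperedges
  and fresh drains on the `m − k′` head vertices that must have outgoing
  ones. The minimal witness realises exactly the parameters of the closed
  form and is acyclic with unique directed paths by construction; both
  hypertree conditions are nevertheless re-verified programmatically (cycle
  detection plus path counting over all ordered pairs);
* `directed_cycle`, `hyperloop`, `weighted_counterexample` — as named;
* `random` — seeded uniform tails/heads with rejection sampling for weak
  connectivity (cap 100 tries, then an error).

Defaults used throughout the test and acceptance runs are desk-scale:
random hypergraphs of 7 vertices and 5 hyperedges with tail/head sizes 1–2,
property suites over 120–200 seeds, hypertree sweeps over all
`(n, m, k, k′)` with `n, m ≤ 4`. These sizes exercise every code path
(hyperloops, parallel edges, unreachable pairs) while each LP stays a few
dozen variables. Passing tests certify the combinatorial theory exactly;
they say nothing about the statistical behaviour of curvature on large
empirical reaction networks, which this package computes but does not
model.

## Numerical choices

* identity and duality tolerances: 1e-9 absolute; measure normalisation is
  exact (rationals) so no tolerance applies there;
* LP negativity clip: −1e-12;
* distance cap inside the engine: 3 (exceeding it is an internal error, as
  it would contradict the support bound);
* the Lipschitz-dual LP fixes no gauge; the objective is shift-invariant
  and the variable box ±100 is inert at these diameters;
* tie-breaks: vertex orders are sorted everywhere, so all outputs are
  deterministic given the input and seed.

## Known limitations

* No out–out curvature variant (it needs strong connectivity, which
  empirical directed networks typically lack) and no multi-marginal
  scalar-curvature variant.
* Curvature is defined only for vertex sets joined by a hyperedge.
* The `literal` hyperloop policy refuses rather than repairs unbalanced
  measures; use `conserve` for hypergraphs with hyperloops.
* No readers for SBML or other metabolic formats; inputs are the `.dhg`
  hyperedge-list format, JSON, or programmatic construction.
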