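"""Transport engine, curvature identities, bounds, closed forms, diagnostics."""

import math
from fractions import Fraction

import pytest

from hyperricci import (
    DirectedHypergraph,
    FamilySpec,
    Hyperedge,
    UnbalancedTransportError,
    build_hypergraph,
    classify_directed_triangles,
    curvature_bounds,
    curvature_spectrum,
    decomposition_identities,
    dual_objective,
    hyperedge_curvature,
    hypertree_closed_form,
    in_measure,
    lipschitz_dual_optimum,
    make_family,
    out_measure,
    perturbation_bound,
    ricci_one_partition,
    ricci1_digraph_gap_instance,
    single_edge_curvature,
    wasserstein_plan,
)
from hyperricci.measures import DiscreteMeasure
from conftest import brute_force_wasserstein, measures_and_dist


def _measure(masses, side="in", eid="synthetic"):
    return DiscreteMeasure({k: Fraction(v) for k, v in masses.items()}, side, eid)


class TestWassersteinPlan:
    def test_identical_measures_cost_zero(self):
        mu = _measure({"a": Fraction(1, 2), "b": Fraction(1, 2)})
        nu = _measure({"a": Fraction(1, 2), "b": Fraction(1, 2)}, side="out")
        d = {(u, v): 0 if u == v else 3 for u in "ab" for v in "ab"}
        W, plan = wasserstein_plan(mu, nu, d)
        assert W == 0
        assert plan.mass("a", "a") == pytest.approx(0.5)

    def test_single_forced_coupling(self):
        W, plan = wasserstein_plan(
            _measure({"u": 1}), _measure({"v": 1}, side="out"), {("u", "v"): 3}
        )
        assert W == 3
        assert plan.mass("u", "v") == pytest.approx(1.0)

    def test_worked_example_fractions_recombine_to_w(self):
        # measures and costs realising the printed decomposition 1/12 at 0,
        # 1/3 at 1, 1/6 at 2, 5/12 at 3 -> W = 23/12
        fr = [Fraction(1, 12), Fraction(1, 3), Fraction(1, 6), Fraction(5, 12)]
        mu = _measure({f"s{i}": fr[i] for i in range(4)})
        nu = _measure({f"t{i}": fr[i] for i in range(4)}, side="out")
        d = {
            (f"s{i}", f"t{j}"): i if i == j else 3
            for i in range(4)
            for j in range(4)
        }
        W, plan = wasserstein_plan(mu, nu, d)
        assert W == pytest.approx(float(Fraction(23, 12)), abs=1e-9)
        assert plan.marginal_defect() < 1e-9

    def test_unbalanced_totals_refused(self):
        with pytest.raises(UnbalancedTransportError):
            wasserstein_plan(
                _measure({"u": 1}),
                _measure({"v": Fraction(1, 2)}, side="out"),
                {("u", "v"): 1},
            )

    def test_infinite_required_distance_is_an_error(self):
        with pytest.raises(ValueError, match="infinite"):
            wasserstein_plan(
                _measure({"u": 1}), _measure({"v": 1}, side="out"),
                {("u", "v"): math.inf},
            )

    def test_matches_brute_force_on_small_instances(self, chain, two_shared_cycles):
        for H, eid in [(chain, "e1"), (two_shared_cycles, "designated")]:
            mu, nu, d = measures_and_dist(H, eid)
            W, _ = wasserstein_plan(mu, nu, d)
            assert W == pytest.approx(float(brute_force_wasserstein(mu, nu, d)), abs=1e-9)


class TestDecompositionIdentities:
    def test_printed_fractions_give_minus_eleven_twelfths(self):
        mu = [Fraction(1, 12), Fraction(1, 3), Fraction(1, 6), Fraction(5, 12)]
        total, W, kappa = decomposition_identities(mu)
        assert total == 1
        assert W == Fraction(23, 12)
        assert kappa == Fraction(-11, 12)

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            decomposition_identities([1.0, 0.0, 0.0])


class TestHyperedgeCurvature:
    def test_isolated_hyperedge_is_flat(self):
        H = build_hypergraph([({"x1", "x2"}, {"y1", "y2", "y3"})])
        r = hyperedge_curvature(H, "e0")
        assert r.kappa == pytest.approx(0.0, abs=1e-9)
        assert r.mu1 == pytest.approx(1.0, abs=1e-9)

    def test_chain_reaches_minimum_curvature(self, chain):
        r = hyperedge_curvature(chain, "e1")
        assert r.kappa == pytest.approx(-2.0, abs=1e-9)
        assert r.mu3 == pytest.approx(1.0, abs=1e-9)

    def test_full_hyperloop_reaches_maximum_curvature(self):
        H = build_hypergraph([({"x1", "x2", "x3"}, {"x1", "x2", "x3"})])
        r = hyperedge_curvature(H, "e0")
        assert r.kappa == pytest.approx(1.0, abs=1e-9)
        assert r.mu0 == pytest.approx(1.0, abs=1e-9)

    def test_literal_policy_refuses_unbalanced_hyperloop(self):
        H = build_hypergraph([({"x"}, {"x", "y"})])
        with pytest.raises(UnbalancedTransportError):
            hyperedge_curvature(H, "e0", policy="literal")

    def test_conserve_policy_handles_the_same_hyperloop(self):
        H = build_hypergraph([({"x"}, {"x", "y"})])
        r = hyperedge_curvature(H, "e0")
        assert -2 - 1e-9 <= r.kappa <= 1 + 1e-9

    def test_disconnected_input_rejected(self):
        H = build_hypergraph([({"a"}, {"b"}), ({"c"}, {"d"})])
        with pytest.raises(ValueError, match="weakly connected"):
            hyperedge_curvature(H, "e0")

    def test_curvature_can_exceed_max_over_corresponding_edges(self):
        # a set-valued hyperedge with kappa = 1 while each of its induced
        # single edges has kappa = -1/2: the max over corresponding edges
        # is no upper bound, only the min is a lower bound
        H = ricci1_digraph_gap_instance()
        r = hyperedge_curvature(H, "e")
        assert r.kappa == pytest.approx(1.0, abs=1e-9)
        own = [single_edge_curvature(H, x, "y").kappa for x in ("x1", "x2")]
        assert own == pytest.approx([-0.5, -0.5], abs=1e-9)
        assert max(own) < r.kappa - 1e-9


class TestBounds:
    def test_hyperloop_upper_bound_is_tight(self):
        H = build_hypergraph([({"x1", "x2", "x3"}, {"x1", "x2", "x3"})])
        lower, upper = curvature_bounds(H, "e0")
        r = hyperedge_curvature(H, "e0")
        assert upper == pytest.approx(1.0, abs=1e-9) == pytest.approx(r.kappa)
        assert lower <= r.kappa + 1e-9

    def test_chain_lower_bound_is_tight(self, chain):
        lower, upper = curvature_bounds(chain, "e1")
        assert lower == pytest.approx(-2.0, abs=1e-9)
        assert lower - 1e-9 <= hyperedge_curvature(chain, "e1").kappa <= upper + 1e-9

    def test_complete_tripartite_digraph_lower_bound_is_one(self):
        H = make_family(FamilySpec("ricci1_tripartite_digraph", sizes=(2, 2, 2)))
        lower, upper = curvature_bounds(H, H.hyperedges[0])
        assert lower == pytest.approx(1.0, abs=1e-9)


class TestDualObjective:
    def test_constant_function_gives_zero(self, chain):
        mu, nu, d = measures_and_dist(chain, "e1")
        f = {v: 5.0 for v in chain.vertex_ids}
        assert dual_objective(f, mu, nu, d) == pytest.approx(0.0)

    def test_hypertree_witness_attains_w(self, chain):
        # 3 on tails of incoming hyperedges, 2 on A, 1 on B, 0 elsewhere
        f = {"u": 3.0, "x": 2.0, "y": 1.0, "v": 0.0}
        mu, nu, d = measures_and_dist(chain, "e1")
        value = dual_objective(f, mu, nu, d)
        assert value == pytest.approx(3.0)  # = W at k = k' = 0, n = m = 1

    @pytest.mark.parametrize(
        "n,m,k,kp", [(2, 2, 0, 0), (3, 2, 1, 1), (4, 3, 2, 0), (1, 1, 1, 1)]
    )
    def test_hypertree_witness_value_matches_formula(self, n, m, k, kp):
        H = make_family(FamilySpec("hypertree", n=n, m=m, k=k, k_prime=kp))
        mu, nu, d = measures_and_dist(H, "designated")
        f = {v: 0.0 for v in H.vertex_ids}
        for x in H.hyperedge("designated").tail:
            f[x] = 2.0
            for ep in H.in_hyperedges(x):
                for z in ep.tail:
                    f[z] = 3.0
        for y in H.hyperedge("designated").head:
            f[y] = 1.0
        value = dual_objective(f, mu, nu, d)
        assert value == pytest.approx(3 - k / n - kp / m, abs=1e-12)

    def test_infeasible_function_reports_a_pair(self, chain):
        mu, nu, d = measures_and_dist(chain, "e1")
        f = {"u": 10.0, "v": 0.0, "x": 0.0, "y": 0.0}
        with pytest.raises(ValueError, match="Lipschitz"):
            dual_objective(f, mu, nu, d)

    def test_symmetric_case_dual_equals_w(self):
        # add a reverse hyperedge for every hyperedge: distances symmetrise
        # and the single-potential dual supremum attains W
        base = [({"a", "b"}, {"c"}), ({"c"}, {"d"}), ({"d"}, {"a", "b"})]
        specs = base + [(h, t) for t, h in base]
        H = build_hypergraph(specs)
        for e in H.hyperedges:
            r = hyperedge_curvature(H, e)
            assert lipschitz_dual_optimum(H, e) == pytest.approx(r.W, abs=1e-9)


class TestClosedFormsAndPerturbations:
    @pytest.mark.parametrize(
        "args,want",
        [
            ((1, 1, 0, 0), Fraction(-2)),
            ((2, 2, 2, 2), Fraction(0)),
            ((2, 2, 1, 1), Fraction(-1)),
            ((3, 2, 1, 1), Fraction(-7, 6)),
        ],
    )
    def test_hypertree_closed_form_values(self, args, want):
        assert hypertree_closed_form(*args) == want

    @pytest.mark.parametrize("args", [(0, 1, 0, 0), (2, 2, 3, 0), (2, 2, 0, -1)])
    def test_hypertree_closed_form_range_errors(self, args):
        with pytest.raises(ValueError):
            hypertree_closed_form(*args)

    def test_perturbation_bounds(self, chain):
        r = hyperedge_curvature(
            build_hypergraph([({"a", "b", "c"}, {"y"})]), "e0"
        )
        assert perturbation_bound(r, "remove", 1, 0).bound == pytest.approx(1.0)
        assert perturbation_bound(r, "remove", 0, 0).bound == 0.0
        r11 = hyperedge_curvature(chain, "e1")
        assert perturbation_bound(r11, "extend", 1, 1).bound == pytest.approx(3.0)

    def test_removal_emptying_a_side_rejected(self, chain):
        r = hyperedge_curvature(chain, "e1")
        with pytest.raises(ValueError, match="empty"):
            perturbation_bound(r, "remove", 1, 0)


class TestTriangles:
    def test_mu0_triangle_and_curvature_one(self):
        H = build_hypergraph([({"u"}, {"x"}), ({"x"}, {"y"}), ({"y"}, {"u"})])
        report = classify_directed_triangles(H, "e1")
        assert report.count("mu0_type") == 1
        assert hyperedge_curvature(H, "e1").kappa == pytest.approx(1.0, abs=1e-9)

    def test_mu2_tail_triangle(self):
        H = build_hypergraph([({"x"}, {"u"}), ({"x"}, {"y"}), ({"y"}, {"u"})])
        report = classify_directed_triangles(H, "e1")
        assert report.count("mu2_tail_type") == 1
        assert report.count("mu0_type") == 0

    def test_mu2_head_triangle(self):
        H = build_hypergraph([({"u"}, {"x"}), ({"u"}, {"y"}), ({"x"}, {"y"})])
        report = classify_directed_triangles(H, "e2")
        assert report.count("mu2_head_type") == 1

    def test_inert_triangle_leaves_curvature_unchanged(self):
        H = build_hypergraph([({"x"}, {"u"}), ({"u"}, {"y"}), ({"x"}, {"y"})])
        report = classify_directed_triangles(H, "e2")
        assert report.count("inert_type") == 1
        # x keeps d_in = 0 and y keeps d_out = 0, so kappa(e2) stays at the
        # isolated-edge value 0: the pink-green triangle has no effect
        assert hyperedge_curvature(H, "e2").kappa == pytest.approx(0.0, abs=1e-9)
        isolated = build_hypergraph([({"x"}, {"y"})])
        assert hyperedge_curvature(isolated, "e0").kappa == pytest.approx(0.0, abs=1e-9)


class TestRicciOnePartition:
    def test_complete_tripartite_digraph_recovers_parts(self):
        H = make_family(FamilySpec("ricci1_tripartite_digraph", sizes=(2, 2, 2)))
        res = ricci_one_partition(H)
        assert res.ok
        parts = {frozenset(s) for s in res.sets}
        assert parts == {
            frozenset({"a0", "a1"}),
            frozenset({"b0", "b1"}),
            frozenset({"c0", "c1"}),
        }

    def test_set_valued_cycle_recovers_parts(self):
        H = make_family(FamilySpec("ricci1_tripartite_hyper", sizes=(2, 3, 2)))
        res = ricci_one_partition(H)
        assert res.ok
        assert sorted(len(s) for s in res.sets) == [2, 2, 3]

    def test_flat_bipartite_is_not_ricci_one(self):
        H = make_family(FamilySpec("flat_bipartite", sizes=(3, 4)))
        res = ricci_one_partition(H)
        assert not res.ok
        assert "kappa" in res.reason

    def test_reverse_hyperedge_precondition(self):
        H = build_hypergraph([({"a"}, {"b"}), ({"b"}, {"a"})])
        res = ricci_one_partition(H)
        assert not res.ok
        assert "reverse" in res.reason


class TestIdentitySuite:
    @pytest.mark.parametrize(
        "family,kwargs",
        [
            ("ricci1_tripartite_hyper", {"sizes": (2, 2, 2)}),
            ("flat_tripartite", {"sizes": (2, 2, 2)}),
            ("negative_four_set", {"sizes": (1, 2, 1, 2)}),
            ("directed_cycle", {"cycle_k": 5}),
            ("hyperloop", {"sizes": (3,)}),
            ("hypertree", {"n": 3, "m": 2, "k": 1, "k_prime": 2}),
        ],
    )
    def test_identities_hold_across_families(self, family, kwargs):
        H = make_family(FamilySpec(family, **kwargs))
        for r in curvature_spectrum(H):
            assert sum(r.mu) == pytest.approx(1.0, abs=1e-9)
            assert sum(i * f for i, f in enumerate(r.mu)) == pytest.approx(r.W, abs=1e-9)
            assert r.mu0 - r.mu2 - 2 * r.mu3 == pytest.approx(r.kappa, abs=1e-9)
            assert -2 - 1e-9 <= r.kappa <= 1 + 1e-9
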