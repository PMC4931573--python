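"""Exact DSH solver: ordered combinations, layers, forest-cover DP, full
solves and co-optimal enumeration against the brute-force oracle."""

import itertools
import math
import random
from fractions import Fraction

import pytest

from multipus.builder import ConsortiumInstance, WeightConfig
from multipus.errors import GuardrailError, ValidationError
from multipus.hypergraph import is_rooted, spreadness
from multipus.oracle import GeneratorParams, brute_force_dsh, generate_random_instance
from multipus.solver import (
    candidate_roots,
    compute_layers,
    enumerate_optimal,
    enumerate_ordered_subsets,
    solve_SH,
    solve_dsh,
)
from multipus.steiner import INF, arc_graph

from conftest import mk_hypergraph, mk_instance


def sweep_params(seed):
    """Mixed oracle-scale regimes: weight policies and insertion presence
    rotate with the seed so ties, insertions and tentacular arcs all occur."""
    weights = [
        WeightConfig(),              # published defaults 1/100/100
        WeightConfig(1, 1, 1),       # unit weights: minimum arc count
        WeightConfig(1, 3, 2),       # tie-rich small weights
    ][seed % 3]
    return GeneratorParams(
        seed=seed,
        weights=weights,
        n_reference_reactions=seed % 2,
        tentacular_fraction=0.25,
        feasible=(seed % 7 != 0),
    )


class TestOrderedSubsets:
    @pytest.mark.parametrize("k,expected", [(0, 1), (2, 5), (3, 16)])
    def test_sequence_counts(self, k, expected):
        ids = [f"t{i}" for i in range(k)]
        seqs = list(enumerate_ordered_subsets(ids))
        assert len(seqs) == expected
        assert len(set(seqs)) == expected  # each exactly once
        assert len(seqs) <= 2**k * math.factorial(k)

    def test_k2_exact_sequences(self):
        seqs = list(enumerate_ordered_subsets(["a", "b"]))
        assert seqs == [(), ("a",), ("b",), ("a", "b"), ("b", "a")]

    def test_guardrail_refusal_and_override(self):
        ids = [f"t{i}" for i in range(9)]
        with pytest.raises(GuardrailError):
            list(enumerate_ordered_subsets(ids))
        seqs = enumerate_ordered_subsets(ids, max_k=1, override_guardrail=True)
        assert sum(1 for _ in seqs) == 10


class TestLayers:
    def _h(self):
        return mk_hypergraph(
            [
                ("a1", ["p", "q"], "r", 1),
                ("a2", ["r", "s"], "w", 1),
                ("e1", ["s"], "p", 1),
            ],
            extra_vertices=["t1", "t2"],
        )

    def test_empty_combination(self):
        comb = compute_layers([], {"s"}, {"t1", "t2"}, self._h())
        assert comb.T_prime == {"t1", "t2"}
        assert comb.layer_T == {"t1": 1, "t2": 1}
        assert comb.layer_S == {"s": 0}

    def test_single_arc_layers(self):
        comb = compute_layers(["a1"], {"s"}, {"t1", "p"}, self._h())
        assert comb.layer_T == {"p": 1, "q": 1, "t1": 2}
        assert comb.layer_S == {"s": 0, "r": 1}

    def test_source_precedence_over_tentacular_target(self):
        # s is in S and also the target of nothing; r is target of a1 but
        # also put into S: S wins with layer 0
        comb = compute_layers(["a1"], {"s", "r"}, {"t1"}, self._h())
        assert comb.layer_S["r"] == 0

    def test_non_tentacular_member_rejected(self):
        with pytest.raises(ValidationError):
            compute_layers(["e1"], {"s"}, {"t1"}, self._h())

    def test_candidate_roots_by_hand(self):
        comb = compute_layers(["a1", "a2"], {"s"}, {"t1"}, self._h())
        # Layer_T: p,q -> 1; r,s -> 2 (sources of a2); t1 -> 3
        # Layer_S: s -> 0; r -> 1; w -> 2
        assert candidate_roots(comb, {"p"}) == {"s"}
        assert candidate_roots(comb, {"s"}) == {"s", "r"}
        assert candidate_roots(comb, {"t1"}) == {"s", "r", "w"}
        assert candidate_roots(comb, {"p", "t1"}) == {"s"}

    def test_empty_y_rejected(self):
        comb = compute_layers([], {"s"}, {"t1"}, self._h())
        with pytest.raises(ValidationError):
            candidate_roots(comb, set())


def brute_force_forest_weight(g, comb):
    """Exhaustive minimum weight of a forest covering T' under the layer
    constraints: try every edge subset, require in-degree <= 1, acyclicity,
    leaves in T', and a layer-compatible root per covered target."""
    edge_ids = sorted(g.edges)
    T = comb.T_prime
    best = INF
    for r in range(len(edge_ids) + 1):
        for combo in itertools.combinations(edge_ids, r):
            edges = [g.edges[e] for e in combo]
            indeg = {}
            for e in edges:
                indeg[e.v] = indeg.get(e.v, 0) + 1
            if any(c > 1 for c in indeg.values()):
                continue
            parent = {e.v: e.u for e in edges}

            def root_of(v):
                seen = {v}
                while v in parent:
                    v = parent[v]
                    if v in seen:
                        return None  # cycle
                    seen.add(v)
                return v

            in_forest = set(parent) | set(parent.values())
            outdeg = {}
            for e in edges:
                outdeg[e.u] = outdeg.get(e.u, 0) + 1
            leaves = {v for v in in_forest if outdeg.get(v, 0) == 0}
            if not leaves <= T:
                continue
            ok = True
            for t in T:
                root = root_of(t) if t in in_forest else t
                if root is None or root not in candidate_roots(comb, {t}):
                    ok = False
                    break
            if not ok:
                continue
            w = sum((e.weight for e in edges), Fraction(0))
            if w < best:
                best = w
    return best


class TestForestCover:
    def test_isolated_target_in_sources_costs_zero(self):
        h = mk_hypergraph([("e1", ["s"], "t", 1)])
        comb = compute_layers([], {"s"}, {"s"}, h)
        w, forest = solve_SH(arc_graph(h), comb)
        assert w == 0
        assert forest is not None and forest.edge_ids() == frozenset()

    def test_disconnected_targets_sum_of_paths(self):
        h = mk_hypergraph(
            [("e1", ["s1"], "t1", 2), ("e2", ["s2"], "t2", 3)]
        )
        comb = compute_layers([], {"s1", "s2"}, {"t1", "t2"}, h)
        w, forest = solve_SH(arc_graph(h), comb)
        assert w == 5
        assert forest.edge_ids() == {"e1", "e2"}

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_forest_search(self, seed):
        rng = random.Random(seed + 900)
        arcs = []
        vertices = [f"v{i}" for i in range(6)]
        for i in range(rng.randint(4, 8)):
            k = 2 if rng.random() < 0.25 else 1
            srcs = rng.sample(vertices, k)
            arcs.append(
                (f"a{i}", srcs, rng.choice(vertices), rng.randint(0, 3))
            )
        h = mk_hypergraph(arcs, extra_vertices=vertices)
        tent = h.tentacular_ids()
        m = rng.sample(tent, min(len(tent), rng.randint(0, 1)))
        S = set(rng.sample(vertices, rng.randint(1, 2)))
        T = set(rng.sample(vertices, rng.randint(1, 3)))
        comb = compute_layers(m, S, T, h)
        if len(comb.T_prime) > 4:
            comb = compute_layers([], S, T, h)
        g = arc_graph(h)
        w, forest = solve_SH(g, comb)
        assert w == brute_force_forest_weight(g, comb)
        if w != INF:
            assert sum(
                (g.edges[e].weight for e in forest.edge_ids()), Fraction(0)
            ) <= w  # trees may share nothing at the optimum; never heavier


class TestSolveDsh:
    def test_single_arc_instance(self):
        inst = mk_instance([("e1", ["s"], "t", 5)], S={"s"}, T={"t"})
        out = solve_dsh(inst)
        assert out.feasible and out.optimal_weight == 5
        assert out.solutions[0].arcs == {"e1"}

    def test_forced_tentacular_arc_with_both_supply_paths(self):
        inst = mk_instance(
            [
                ("p_u", ["s"], "u", 1),
                ("p_v", ["s"], "v", 1),
                ("syn", ["u", "v"], "t", 1),
            ],
            S={"s"},
            T={"t"},
        )
        out = solve_dsh(inst)
        assert out.optimal_weight == 3
        assert out.solutions[0].arcs == {"p_u", "p_v", "syn"}
        assert out.combinations_used[0] == ("syn",)

    def test_infeasible_is_outcome_not_exception(self):
        inst = mk_instance(
            [("e1", ["s"], "a", 1)], S={"s"}, T={"t"}, extra_vertices=["t"]
        )
        out = solve_dsh(inst)
        assert out.status == "infeasible"
        assert out.optimal_weight is None and out.solutions == []

    def test_source_target_strict_vs_lenient(self):
        # t is a source; strict semantics require it to be produced anyway
        inst = mk_instance(
            [("prod_t", ["s"], "t", 4), ("other", ["t"], "x", 1)],
            S={"s", "t"},
            T={"t"},
        )
        strict = solve_dsh(inst)
        assert strict.optimal_weight == 4
        assert strict.solutions[0].arcs == {"prod_t"}
        lenient = solve_dsh(inst, allow_source_targets=True)
        assert lenient.optimal_weight == 0
        assert lenient.solutions[0].arcs == frozenset()

    def test_source_target_unproducible_is_infeasible_strict_only(self):
        inst = mk_instance(
            [("other", ["t"], "x", 1)], S={"t"}, T={"t"}
        )
        assert solve_dsh(inst).status == "infeasible"
        assert solve_dsh(inst, allow_source_targets=True).feasible

    def test_unit_weights_minimise_arc_count(self):
        for seed in range(15):
            inst = generate_random_instance(
                GeneratorParams(seed=seed + 300, weights=WeightConfig(1, 1, 1))
            )
            out = solve_dsh(inst)
            oracle = brute_force_dsh(inst)
            assert out.optimal_weight == oracle.optimal_weight
            if out.feasible:
                assert out.optimal_weight == len(out.solutions[0].arcs)

    def test_optimum_invariant_under_vertex_relabeling(self):
        inst = generate_random_instance(GeneratorParams(seed=123))
        base = solve_dsh(inst).optimal_weight

        from multipus.hypergraph import Hypergraph, Hyperarc, Vertex

        rename = {v: f"zz_{v}" for v in inst.hypergraph.vertices}
        h2 = Hypergraph()
        for v in inst.hypergraph.vertices.values():
            h2.add_vertex(Vertex(rename[v.id], v.compound_id, v.organism))
        for a in inst.hypergraph.hyperarcs.values():
            h2.add_arc(
                Hyperarc(
                    a.id,
                    a.reaction_id,
                    frozenset(rename[s] for s in a.sources),
                    rename[a.target],
                    a.weight,
                    a.category,
                    a.organism,
                )
            )
        inst2 = ConsortiumInstance(
            hypergraph=h2,
            S=frozenset(rename[s] for s in inst.S),
            T=frozenset(rename[t] for t in inst.T),
            weights=inst.weights,
        )
        assert solve_dsh(inst2).optimal_weight == base

    def test_weight_increase_never_decreases_optimum(self):
        from dataclasses import replace

        for seed in (11, 12, 13, 14):
            inst = generate_random_instance(sweep_params(seed))
            out = solve_dsh(inst)
            if not out.feasible:
                continue
            aid = sorted(inst.hypergraph.hyperarcs)[seed % len(inst.hypergraph.hyperarcs)]
            h2 = inst.hypergraph.copy()
            a = h2.hyperarcs[aid]
            h2.hyperarcs[aid] = replace(a, weight=a.weight + 7)
            inst2 = replace(inst, hypergraph=h2)
            assert solve_dsh(inst2).optimal_weight >= out.optimal_weight


class TestEnumerateOptimal:
    def test_unique_solution_instance(self):
        inst = mk_instance([("e1", ["s"], "t", 5)], S={"s"}, T={"t"})
        out = enumerate_optimal(inst, cap=10)
        assert len(out.solutions) == 1 and not out.truncated

    def test_two_parallel_equal_arcs_give_two_solutions(self):
        inst = mk_instance(
            [("e1", ["s"], "t", 2), ("e2", ["s"], "t", 2)], S={"s"}, T={"t"}
        )
        out = enumerate_optimal(inst, cap=10)
        assert {s.key() for s in out.solutions} == {("e1",), ("e2",)}

    def test_cap_truncates_and_flags(self, diamond_graph_arcs):
        inst = mk_instance(diamond_graph_arcs, S={"s"}, T={"t"})
        full = enumerate_optimal(inst, cap=10)
        assert len(full.solutions) == 2 and not full.truncated
        capped = enumerate_optimal(inst, cap=1)
        assert len(capped.solutions) == 1 and capped.truncated

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_oracle_weight_and_solution_set(self, seed):
        inst = generate_random_instance(sweep_params(seed + 40_000))
        oracle = brute_force_dsh(inst)
        solved = enumerate_optimal(inst, cap=5000)
        assert solved.status == oracle.status
        if oracle.feasible:
            assert solved.optimal_weight == oracle.optimal_weight
            assert {s.key() for s in solved.solutions} == {
                s.key() for s in oracle.solutions
            }


class TestStructuralInvariants:
    @pytest.mark.parametrize("seed", range(40))
    def test_every_solution_validates(self, seed):
        inst = generate_random_instance(sweep_params(seed + 60_000))
        out = enumerate_optimal(inst, cap=500)
        if not out.feasible:
            return
        h = inst.hypergraph
        for sol in out.solutions:
            ok, ordering = is_rooted(h, sol.arcs, inst.S)
            assert ok and sorted(ordering) == sorted(sol.arcs)
            assert inst.T <= h.targets_of(sol.arcs)
            # plain-arc part is a forest (in-degree <= 1 per vertex)
            indeg = {}
            for aid in sol.arcs:
                a = h.hyperarcs[aid]
                if spreadness(a) == 1:
                    indeg[a.target] = indeg.get(a.target, 0) + 1
            assert all(c <= 1 for c in indeg.values())
            # inclusion-minimal: no arc is removable
            for aid in sol.arcs:
                rest = sol.arcs - {aid}
                still_ok, _ = is_rooted(h, rest, inst.S)
                assert not (still_ok and inst.T <= h.targets_of(rest))
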