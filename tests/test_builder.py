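"""Instance construction: disjoint union, insertions, transitions, cofactor
filtering, and the lossless pre-solve compression."""

from fractions import Fraction

import pytest

from multipus.builder import (
    WeightConfig,
    add_insertion_arcs,
    add_transition_arcs,
    build_instance,
    compress,
    expand_solution,
    merge_worker_networks,
    remove_cofactors,
)
from multipus.errors import InfeasibleInstanceError, ValidationError
from multipus.hypergraph import (
    ENDOGENOUS,
    INSERTION,
    TRANSITION,
    Reaction,
    is_rooted,
)
from multipus.oracle import GeneratorParams, brute_force_dsh, generate_random_instance
from multipus.solver import enumerate_optimal

from conftest import mk_instance


def chain(prefix, names):
    return [
        Reaction(f"{prefix}{i}", (a,), (b,))
        for i, (a, b) in enumerate(zip(names, names[1:]))
    ]


class TestMerge:
    def test_disjoint_union_counts_and_weights(self):
        nets = [
            ("A", chain("a", ["c1", "c2", "c3", "c4"])),
            ("B", chain("b", ["d1", "d2", "d3", "d4"])),
        ]
        inst = merge_worker_networks(nets, WeightConfig(w_worker=2))
        h = inst.hypergraph
        assert len(h.hyperarcs) == 6
        assert all(a.category == ENDOGENOUS for a in h.hyperarcs.values())
        assert all(a.weight == 2 for a in h.hyperarcs.values())
        assert len(h.vertices) == 8

    def test_single_organism_is_its_own_hypergraph(self):
        inst = merge_worker_networks([("A", chain("a", ["x", "y", "z"]))])
        assert set(inst.hypergraph.vertices) == {"x@A", "y@A", "z@A"}
        assert inst.worker_organisms == ("A",)

    def test_shared_compounds_get_distinct_vertices(self):
        nets = [
            ("A", [Reaction("r1", ("glc",), ("pyr",))]),
            ("B", [Reaction("r2", ("glc",), ("pyr",))]),
        ]
        h = merge_worker_networks(nets).hypergraph
        assert {"glc@A", "glc@B", "pyr@A", "pyr@B"} <= set(h.vertices)

    def test_duplicate_organism_and_empty_network_rejected(self):
        net = [("A", chain("a", ["x", "y"]))]
        with pytest.raises(ValidationError, match="duplicate organism"):
            merge_worker_networks(net + net)
        with pytest.raises(ValidationError, match="empty network"):
            merge_worker_networks([("A", [])])


class TestInsertions:
    def test_reference_reaction_copied_into_worker(self):
        inst = merge_worker_networks([("A", [Reaction("r1", ("x",), ("y",))])])
        inst = add_insertion_arcs(inst, [Reaction("ref1", ("y",), ("z",))])
        ins = [
            a for a in inst.hypergraph.hyperarcs.values()
            if a.category == INSERTION
        ]
        assert len(ins) == 1
        assert ins[0].organism == "A"
        assert ins[0].weight == inst.weights.w_other
        assert "z@A" in inst.hypergraph.vertices  # missing compound created

    def test_reaction_already_present_not_copied(self):
        inst = merge_worker_networks([("A", [Reaction("r1", ("x",), ("y",))])])
        inst = add_insertion_arcs(inst, [Reaction("r1", ("x",), ("y",))])
        assert not any(
            a.category == INSERTION
            for a in inst.hypergraph.hyperarcs.values()
        )

    def test_copies_only_into_workers_missing_the_reaction(self):
        nets = [("W1", [Reaction("shared", ("x",), ("y",))])] + [
            (f"W{i}", [Reaction(f"r{i}", ("x",), ("y",))]) for i in (2, 3, 4)
        ]
        inst = merge_worker_networks(nets)
        inst = add_insertion_arcs(inst, [Reaction("shared", ("x",), ("y",))])
        ins = [
            a for a in inst.hypergraph.hyperarcs.values()
            if a.category == INSERTION
        ]
        assert len(ins) == 3
        assert {a.organism for a in ins} == {"W2", "W3", "W4"}


class TestTransitions:
    def _two_org(self):
        return merge_worker_networks(
            [
                ("A", [Reaction("r1", ("c",), ("d",))]),
                ("B", [Reaction("r2", ("c",), ("e",))]),
            ]
        )

    def test_shared_compound_gets_both_directions(self):
        inst = add_transition_arcs(self._two_org())
        trans = {
            a.id: a
            for a in inst.hypergraph.hyperarcs.values()
            if a.category == TRANSITION
        }
        assert set(trans) == {"tr:c:A>B", "tr:c:B>A"}
        for a in trans.values():
            assert a.weight == inst.weights.w_transition

    def test_unshared_compound_gets_no_transition(self):
        inst = add_transition_arcs(self._two_org())
        compounds = {
            inst.hypergraph.vertices[next(iter(a.sources))].compound_id
            for a in inst.hypergraph.hyperarcs.values()
            if a.category == TRANSITION
        }
        assert compounds == {"c"}

    def test_per_compound_override(self):
        weights = WeightConfig(overrides={(TRANSITION, "c"): Fraction(50)})
        inst = merge_worker_networks(
            [
                ("A", [Reaction("r1", ("c",), ("x",)), Reaction("r3", ("x",), ("d",))]),
                ("B", [Reaction("r2", ("c",), ("d",))]),
            ],
            weights,
        )
        inst = add_transition_arcs(inst)
        by_compound = {}
        for a in inst.hypergraph.hyperarcs.values():
            if a.category == TRANSITION:
                cid = inst.hypergraph.vertices[a.target].compound_id
                by_compound[cid] = a.weight
        assert by_compound == {"c": Fraction(50), "d": Fraction(100)}


class TestCofactors:
    def test_cofactors_removed_from_both_sides(self):
        kept, dropped = remove_cofactors(
            [Reaction("r", ("atp", "glc"), ("adp", "g6p"))], {"atp", "adp"}
        )
        assert kept == [Reaction("r", ("glc",), ("g6p",))]
        assert dropped == []

    def test_reaction_reduced_to_empty_side_dropped_and_reported(self):
        kept, dropped = remove_cofactors(
            [Reaction("r", ("atp",), ("x",))], {"atp"}
        )
        assert kept == [] and dropped == ["r"]

    def test_empty_cofactor_list_is_identity(self):
        rxns = [Reaction("r", ("a",), ("b",))]
        assert remove_cofactors(rxns, set()) == (rxns, [])


class TestStructureInvariants:
    def test_single_worker_no_refs_means_no_insertion_no_transition(self):
        inst = build_instance(
            [("A", chain("a", ["x", "y", "z"]))],
            sources=["x@A"],
            targets=["z@A"],
        )
        cats = {a.category for a in inst.hypergraph.hyperarcs.values()}
        assert cats == {ENDOGENOUS}

    def test_endogenous_arc_count_is_sum_over_organisms(self):
        nets = [
            ("A", chain("a", ["x", "y", "z"])),
            ("B", chain("b", ["x", "p", "q"])),
        ]
        inst = build_instance(nets, sources=["x@A"], targets=["z@A"])
        endo = [
            a for a in inst.hypergraph.hyperarcs.values()
            if a.category == ENDOGENOUS
        ]
        assert len(endo) == 4


class TestCompression:
    def test_chain_contracts_to_single_arc(self):
        inst = mk_instance(
            [("e1", ["s"], "a", 1), ("e2", ["a"], "b", 1), ("e3", ["b"], "t", 1)],
            S={"s"},
            T={"t"},
        )
        cinst, emap = compress(inst)
        arcs = list(cinst.hypergraph.hyperarcs.values())
        assert len(arcs) == 1
        assert arcs[0].weight == 3
        assert set(emap.mapping[arcs[0].id]) == {"e1", "e2", "e3"}

    def test_vertex_with_two_incoming_arcs_not_contracted(self):
        inst = mk_instance(
            [
                ("e1", ["s"], "a", 1),
                ("e2", ["s"], "a", 2),
                ("e3", ["a"], "t", 1),
            ],
            S={"s"},
            T={"t"},
        )
        cinst, emap = compress(inst)
        assert len(cinst.hypergraph.hyperarcs) == 3
        assert emap.mapping == {}

    def test_unproducible_target_raises_infeasible(self):
        inst = mk_instance(
            [("e1", ["s"], "a", 1)], S={"s"}, T={"t"}, extra_vertices=["t"]
        )
        with pytest.raises(InfeasibleInstanceError):
            compress(inst)

    def test_useless_branches_pruned(self):
        inst = mk_instance(
            [
                ("e1", ["s"], "t", 1),
                ("dead_in", ["x"], "y", 1),   # never producible
                ("dead_out", ["s"], "z", 1),  # never useful
            ],
            S={"s"},
            T={"t"},
        )
        cinst, _ = compress(inst)
        assert set(cinst.hypergraph.hyperarcs) == {"e1"}

    def test_expand_identity_and_chain_roundtrip(self):
        inst = mk_instance(
            [("e1", ["s"], "a", 1), ("e2", ["a"], "b", 1), ("e3", ["b"], "t", 1)],
            S={"s"},
            T={"t"},
        )
        cinst, emap = compress(inst)
        out = enumerate_optimal(cinst, cap=10)
        assert out.optimal_weight == 3
        expanded = expand_solution(out.solutions[0], emap, inst)
        assert expanded.arcs == {"e1", "e2", "e3"}
        assert expanded.total_weight == 3
        ok, _ = is_rooted(inst.hypergraph, expanded.arcs, inst.S)
        assert ok

    def test_expand_rejects_unknown_arc(self):
        inst = mk_instance([("e1", ["s"], "t", 1)], S={"s"}, T={"t"})
        _, emap = compress(inst)
        from multipus.hypergraph import SolutionHypertree

        fake = SolutionHypertree(
            frozenset({"ghost"}), ("ghost",), Fraction(0), {}
        )
        with pytest.raises(ValidationError):
            expand_solution(fake, emap, inst)

    @pytest.mark.parametrize("seed", range(30))
    def test_compression_preserves_optimum_oracle_checked(self, seed):
        params = GeneratorParams(
            seed=seed + 5000,
            n_reactions_per_organism=4,
            tentacular_fraction=0.3,
            max_total_arcs=12,
            weights=WeightConfig(1, 3, 2),
            feasible=(seed % 5 != 0),
        )
        inst = generate_random_instance(params)
        oracle = brute_force_dsh(inst)
        try:
            cinst, emap = compress(inst)
        except InfeasibleInstanceError:
            assert not oracle.feasible
            return
        solved = enumerate_optimal(cinst, cap=2000)
        assert solved.status == oracle.status
        if oracle.feasible:
            assert solved.optimal_weight == oracle.optimal_weight
            expanded = {
                expand_solution(s, emap, inst).key() for s in solved.solutions
            }
            assert expanded == {s.key() for s in oracle.solutions}
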