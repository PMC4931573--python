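"""Shared helpers: compact hypergraph literals and independent mini-oracles."""

from __future__ import annotations

import itertools
from fractions import Fraction

import pytest

from multipus.builder import ConsortiumInstance, WeightConfig
from multipus.hypergraph import (
    ENDOGENOUS,
    Hyperarc,
    Hypergraph,
    Vertex,
)


def mk_hypergraph(arcs, extra_vertices=()):
    """Build a single-organism hypergraph from compact arc literals.

    ``arcs`` is an iterable of ``(id, sources, target, weight)``; vertex ids
    are used verbatim (compound id == vertex id, organism ``o``).
    """
    h = Hypergraph()

    def ensure(vid):
        if vid not in h.vertices:
            h.add_vertex(Vertex(vid, vid, "o"))

    for vid in extra_vertices:
        ensure(vid)
    for aid, sources, target, weight in arcs:
        for s in sources:
            ensure(s)
        ensure(target)
        h.add_arc(
            Hyperarc(
                aid,
                aid,
                frozenset(sources),
                target,
                Fraction(weight),
                ENDOGENOUS,
                "o",
            )
        )
    return h


def mk_instance(arcs, S, T, extra_vertices=(), weights=None):
    h = mk_hypergraph(arcs, extra_vertices)
    return ConsortiumInstance(
        hypergraph=h,
        S=frozenset(S),
        T=frozenset(T),
        weights=weights or WeightConfig(),
    )


def rooted_by_some_permutation(h, arc_ids, sources):
    """Exhaustive independent check of Definition-3 rootedness: try every
    ordering of the arcs (only usable for small arc sets)."""
    ids = list(arc_ids)
    for perm in itertools.permutations(ids):
        avail = set(sources)
        ok = True
        for aid in perm:
            a = h.hyperarcs[aid]
            if not a.sources <= avail:
                ok = False
                break
            avail.add(a.target)
        if ok:
            return True
    return not ids  # empty set is vacuously rooted


@pytest.fixture
def diamond_graph_arcs():
    """s -> a -> t and s -> b -> t, equal weights: two co-optimal paths."""
    return [
        ("e_sa", ["s"], "a", 1),
        ("e_at", ["a"], "t", 1),
        ("e_sb", ["s"], "b", 1),
        ("e_bt", ["b"], "t", 1),
    ]
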