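"""Build consortium-design instances from per-organism reaction sets.

The construction mirrors how a consortium is modelled: the worker networks
are disjointly unioned (same compound in two organisms gives two distinct
vertices); every reference reaction absent from a worker is copied into it
as an *insertion* arc at cost ``w_other``; every compound present in two
organisms gets a pair of *transition* arcs (one per direction) at cost
``w_transition``.  Endogenous worker reactions cost ``w_worker``.  Typically
``w_other, w_transition >> w_worker``: heterologous expression and transport
are expensive, internal chemistry is nearly free.

A lossless pre-solve reduction (`compress`) removes vertices that can never
be produced from the sources, removes vertices that cannot contribute to any
target, and contracts unbranched single-source chains; an `ExpansionMap`
restores original arcs in solutions of the compressed instance.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional, Union

from .errors import InfeasibleInstanceError, ValidationError
from .hypergraph import (
    ENDOGENOUS,
    INSERTION,
    TRANSITION,
    Hyperarc,
    Hypergraph,
    Reaction,
    SolutionHypertree,
    as_weight,
    closure,
    decompose_reactions,
    spreadness,
    vertex_id,
)


@dataclass(frozen=True)
class WeightConfig:
    """Arc-weight policy.

    ``overrides`` maps ``(category, key)`` to a weight, where ``key`` is a
    compound id for transitions and a reaction id for endogenous/insertion
    arcs — e.g. ``("transition", "acetate"): 50`` makes moving acetate
    between organisms cheaper than the generic transport cost.
    """

    w_worker: Fraction = Fraction(1)
    w_other: Fraction = Fraction(100)
    w_transition: Fraction = Fraction(100)
    overrides: Mapping[tuple[str, str], Fraction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "w_worker", as_weight(self.w_worker))
        object.__setattr__(self, "w_other", as_weight(self.w_other))
        object.__setattr__(self, "w_transition", as_weight(self.w_transition))
        object.__setattr__(
            self,
            "overrides",
            {
                (cat, key): as_weight(w)
                for (cat, key), w in dict(self.overrides).items()
            },
        )

    def endogenous_weight(self, reaction_id: str) -> Fraction:
        return self.overrides.get((ENDOGENOUS, reaction_id), self.w_worker)

    def insertion_weight(self, reaction_id: str) -> Fraction:
        return self.overrides.get((INSERTION, reaction_id), self.w_other)

    def transition_weight(self, compound_id: str) -> Fraction:
        return self.overrides.get((TRANSITION, compound_id), self.w_transition)


@dataclass
class ConsortiumInstance:
    """A complete solver input: hypergraph, sources S, targets T, weights."""

    hypergraph: Hypergraph
    S: frozenset[str] = frozenset()
    T: frozenset[str] = frozenset()
    weights: WeightConfig = field(default_factory=WeightConfig)
    worker_organisms: tuple[str, ...] = ()
    reference_reaction_ids: tuple[str, ...] = ()

    def validate(self, require_targets: bool = True) -> None:
        h = self.hypergraph
        h._check_vertices(self.S)
        h._check_vertices(self.T)
        if require_targets and not self.T:
            raise ValidationError("instance has no targets")

    def with_terminals(
        self, sources: Iterable[str], targets: Iterable[str]
    ) -> "ConsortiumInstance":
        """Return a copy with S and T set (vertex ids ``compound@organism``)."""
        inst = replace(
            self,
            S=self.hypergraph._check_vertices(sources),
            T=self.hypergraph._check_vertices(targets),
        )
        return inst


# ---------------------------------------------------------------------------
# Pipeline steps
# ---------------------------------------------------------------------------

Networks = Union[
    Mapping[str, Sequence[Reaction]],
    Sequence[tuple[str, Sequence[Reaction]]],
]


def _network_items(networks: Networks) -> list[tuple[str, Sequence[Reaction]]]:
    items = (
        list(networks.items())
        if isinstance(networks, Mapping)
        else list(networks)
    )
    seen: set[str] = set()
    for org, _ in items:
        if org in seen:
            raise ValidationError(f"duplicate organism id {org!r}")
        seen.add(org)
    if not items:
        raise ValidationError("at least one worker network is required")
    return items


def merge_worker_networks(
    networks: Networks, weights: Optional[WeightConfig] = None
) -> ConsortiumInstance:
    """Disjoint union of the worker networks.

    Vertices are (compound, organism) pairs — a compound shared by two
    organisms yields two distinct vertices.  All arcs are endogenous at
    ``w_worker`` (modulo per-reaction overrides).  No cross-organism arcs yet.
    """
    weights = weights or WeightConfig()
    items = _network_items(networks)
    h = Hypergraph()
    for org, reactions in items:
        if not list(reactions):
            raise ValidationError(f"organism {org!r} has an empty network")
        for step in decompose_reactions(reactions):
            srcs = frozenset(h.ensure_vertex(c, org).id for c in step.sources)
            tgt = h.ensure_vertex(step.target, org).id
            h.add_arc(
                Hyperarc(
                    f"{step.reaction_id}>{step.target}@{org}",
                    step.reaction_id,
                    srcs,
                    tgt,
                    weights.endogenous_weight(step.reaction_id),
                    ENDOGENOUS,
                    org,
                )
            )
    return ConsortiumInstance(
        hypergraph=h,
        weights=weights,
        worker_organisms=tuple(org for org, _ in items),
    )


def add_insertion_arcs(
    instance: ConsortiumInstance,
    reference_reactions: Sequence[Reaction],
    weights: Optional[WeightConfig] = None,
) -> ConsortiumInstance:
    """Copy every reference reaction absent from a worker into that worker.

    Copies are created eagerly for all workers; compression later prunes the
    useless ones.  Reaction identity is exact ``reaction_id`` equality on the
    directed (reversibility-split) form.  Compound vertices missing from the
    receiving organism are created.  Insertion arcs cost ``w_other``.
    """
    weights = weights or instance.weights
    h = instance.hypergraph.copy()
    steps = decompose_reactions(reference_reactions)
    present: dict[str, set[str]] = {org: set() for org in instance.worker_organisms}
    for a in h.hyperarcs.values():
        if a.category == ENDOGENOUS:
            present[a.organism].add(a.reaction_id)
    for org in instance.worker_organisms:
        for step in steps:
            if step.reaction_id in present[org]:
                continue
            srcs = frozenset(h.ensure_vertex(c, org).id for c in step.sources)
            tgt = h.ensure_vertex(step.target, org).id
            h.add_arc(
                Hyperarc(
                    f"ins:{step.reaction_id}>{step.target}@{org}",
                    step.reaction_id,
                    srcs,
                    tgt,
                    weights.insertion_weight(step.reaction_id),
                    INSERTION,
                    org,
                )
            )
    ref_ids = tuple(sorted({s.reaction_id for s in steps}))
    return replace(
        instance, hypergraph=h, weights=weights, reference_reaction_ids=ref_ids
    )


def add_transition_arcs(
    instance: ConsortiumInstance, weights: Optional[WeightConfig] = None
) -> ConsortiumInstance:
    """Connect every compound present in two organisms by a pair of directed
    transition arcs (one each way) at ``w_transition`` (or its per-compound
    override).  No self-transitions."""
    weights = weights or instance.weights
    h = instance.hypergraph.copy()
    by_compound: dict[str, list[str]] = {}
    for v in h.vertices.values():
        by_compound.setdefault(v.compound_id, []).append(v.organism)
    for compound in sorted(by_compound):
        orgs = sorted(set(by_compound[compound]))
        if len(orgs) < 2:
            continue
        w = weights.transition_weight(compound)
        for o1 in orgs:
            for o2 in orgs:
                if o1 == o2:
                    continue
                h.add_arc(
                    Hyperarc(
                        f"tr:{compound}:{o1}>{o2}",
                        f"transition:{compound}",
                        frozenset({vertex_id(compound, o1)}),
                        vertex_id(compound, o2),
                        w,
                        TRANSITION,
                        (o1, o2),
                    )
                )
    return replace(instance, hypergraph=h, weights=weights)


def remove_cofactors(
    reactions: Sequence[Reaction], cofactor_ids: Iterable[str]
) -> tuple[list[Reaction], list[str]]:
    """Delete ubiquitous cofactors/co-enzymes from substrate and product
    lists; drop (and report) reactions left with an empty side.

    Applied before decomposition, so a reaction whose only substrate is a
    cofactor disappears rather than becoming source-less.
    """
    cof = set(cofactor_ids)
    kept: list[Reaction] = []
    dropped: list[str] = []
    for r in reactions:
        subs = tuple(c for c in r.substrates if c not in cof)
        prods = tuple(c for c in r.products if c not in cof)
        if not subs or not prods:
            dropped.append(r.reaction_id)
            continue
        kept.append(Reaction(r.reaction_id, subs, prods, r.reversible))
    return kept, dropped


def build_instance(
    networks: Networks,
    sources: Iterable[str],
    targets: Iterable[str],
    reference_reactions: Sequence[Reaction] = (),
    weights: Optional[WeightConfig] = None,
    cofactor_ids: Iterable[str] = (),
) -> ConsortiumInstance:
    """Full pipeline: cofactor filtering, disjoint union, insertion copies,
    transition arcs, then terminal selection.  ``sources`` / ``targets`` are
    vertex ids (``compound@organism``)."""
    weights = weights or WeightConfig()
    cof = set(cofactor_ids)
    items = [
        (org, remove_cofactors(list(rxns), cof)[0])
        for org, rxns in _network_items(networks)
    ]
    refs, _ = remove_cofactors(list(reference_reactions), cof)
    inst = merge_worker_networks(items, weights)
    if refs:
        inst = add_insertion_arcs(inst, refs, weights)
    if len(inst.worker_organisms) > 1:
        inst = add_transition_arcs(inst, weights)
    return inst.with_terminals(sources, targets)


# ---------------------------------------------------------------------------
# Lossless compression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpansionMap:
    """Maps each contracted arc id to the ordered original arcs it replaces."""

    mapping: Mapping[str, tuple[str, ...]]

    def expand_arc_ids(self, arc_ids: Iterable[str]) -> list[str]:
        out: list[str] = []
        for aid in arc_ids:
            out.extend(self.mapping.get(aid, (aid,)))
        return out


def compress(
    instance: ConsortiumInstance,
    protect: Optional[Iterable[str]] = None,
) -> tuple[ConsortiumInstance, ExpansionMap]:
    """Lossless pre-solve reduction.

    Three provably optimum-preserving rules, applied to a fixpoint:

    1. *Forward pruning*: a vertex outside ``closure(A, S)`` can never be
       produced; drop it and every arc touching it.
    2. *Backward pruning*: a vertex from which no chain of "is a source of
       an arc producing something useful" reaches a target cannot appear in
       any inclusion-minimal solution; drop it likewise.
    3. *Chain contraction*: an unprotected vertex with exactly one incoming
       and one outgoing arc, both single-source endogenous arcs of the same
       organism, and not touching any tentacular arc, is spliced out; the two
       arcs merge with summed weight.

    Rules 1–2 only remove arcs that no minimal solution uses, and rule 3 is
    a bijection on solutions, so the optimal weight (and the set of minimal
    optimal solutions, up to expansion) is preserved.

    Raises :class:`InfeasibleInstanceError` when a target is unproducible.
    """
    instance.validate()
    protected = set(protect) if protect is not None else set()
    protected |= set(instance.S) | set(instance.T)
    h = instance.hypergraph

    # rule 1: forward reachability
    producible = closure(h, h.hyperarcs.keys(), instance.S)
    lost = set(instance.T) - producible
    if lost:
        raise InfeasibleInstanceError(
            f"infeasible instance: targets not producible from the sources: "
            f"{sorted(lost)}"
        )
    arcs = {
        aid: a
        for aid, a in h.hyperarcs.items()
        if a.sources <= producible and a.target in producible
    }

    # rule 2: backward usefulness over "source of an arc with useful target"
    useful = set(instance.T)
    changed = True
    while changed:
        changed = False
        for a in arcs.values():
            if a.target in useful and not (a.sources <= useful):
                useful |= a.sources
                changed = True
    arcs = {aid: a for aid, a in arcs.items() if a.target in useful}

    keep = (producible & useful) | protected
    keep &= {v for v in h.vertices}
    new_h = Hypergraph()
    for vid in sorted(keep):
        new_h.add_vertex(h.vertices[vid])
    for aid in sorted(arcs):
        a = arcs[aid]
        if a.sources <= keep and a.target in keep:
            new_h.add_arc(a)

    # rule 3: chain contraction, iterated to a fixpoint
    expansion: dict[str, tuple[str, ...]] = {}
    counter = 0
    while True:
        incoming: dict[str, list[Hyperarc]] = {}
        outgoing: dict[str, list[Hyperarc]] = {}
        tentacle_touched: set[str] = set()
        for a in new_h.hyperarcs.values():
            incoming.setdefault(a.target, []).append(a)
            for s in a.sources:
                outgoing.setdefault(s, []).append(a)
            if spreadness(a) > 1:
                tentacle_touched |= a.sources | {a.target}
        victim = None
        for vid in sorted(new_h.vertices):
            if vid in protected or vid in tentacle_touched:
                continue
            ins = incoming.get(vid, [])
            outs = outgoing.get(vid, [])
            if len(ins) != 1 or len(outs) != 1:
                continue
            a_in, a_out = ins[0], outs[0]
            if spreadness(a_in) > 1 or spreadness(a_out) > 1:
                continue
            if a_in.category != ENDOGENOUS or a_out.category != ENDOGENOUS:
                continue
            if a_in.organism != a_out.organism:
                continue
            (u,) = a_in.sources
            if u == vid or a_out.target == vid or u == a_out.target:
                continue
            victim = (vid, a_in, a_out)
            break
        if victim is None:
            break
        vid, a_in, a_out = victim
        counter += 1
        (chain_src,) = a_in.sources
        merged_id = f"chain{counter}:{chain_src}>{a_out.target}"
        chain = tuple(
            expansion.pop(a_in.id, (a_in.id,)) + expansion.pop(a_out.id, (a_out.id,))
        )
        merged = Hyperarc(
            merged_id,
            merged_id,
            a_in.sources,
            a_out.target,
            a_in.weight + a_out.weight,
            ENDOGENOUS,
            a_in.organism,
        )
        del new_h.hyperarcs[a_in.id]
        del new_h.hyperarcs[a_out.id]
        del new_h.vertices[vid]
        new_h.add_arc(merged)
        expansion[merged_id] = chain

    new_S = frozenset(s for s in instance.S if s in new_h.vertices)
    new_inst = replace(instance, hypergraph=new_h, S=new_S)
    return new_inst, ExpansionMap(expansion)


def expand_solution(
    solution: SolutionHypertree,
    emap: ExpansionMap,
    original: ConsortiumInstance,
) -> SolutionHypertree:
    """Replace contracted arcs by their original chains and re-validate the
    result against the original instance.  Total weight is unchanged."""
    h = original.hypergraph
    out: list[str] = []
    for aid in sorted(solution.arcs):
        if aid in emap.mapping:
            out.extend(emap.mapping[aid])
        elif aid in h.hyperarcs:
            out.append(aid)
        else:
            raise ValidationError(
                f"arc {aid!r} is neither original nor in the expansion map"
            )
    expanded = SolutionHypertree.from_arcs(h, out, original.S)
    if expanded.total_weight != solution.total_weight:
        raise ValidationError(
            "expansion changed the total weight — corrupt expansion map"
        )
    return expanded
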