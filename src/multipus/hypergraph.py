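"""Directed-hypergraph model of multi-organism metabolism.

Vertices are (compound, organism) pairs; hyperarcs are reactions.  A hyperarc
has a non-empty set of source vertices (the substrates) and, after
multi-product decomposition, exactly one target vertex (one product).  A
hyperarc with more than one source is *tentacular*; its *spreadness* is the
number of sources.  The sum of spreadness over tentacular hyperarcs — the
*total spreadness* — together with the number of targets is what the exact
solver is exponential in, so both are tracked explicitly here.

All weights are non-negative rationals (`fractions.Fraction`); totals are
compared exactly, never with a floating tolerance.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Union

from .errors import ValidationError

ENDOGENOUS = "endogenous"
INSERTION = "insertion"
TRANSITION = "transition"
CATEGORIES = (ENDOGENOUS, INSERTION, TRANSITION)

#: arbitrary-precision rational accepted anywhere a weight is expected
WeightLike = Union[int, str, Fraction]


def as_weight(value: WeightLike) -> Fraction:
    """Coerce to a non-negative rational weight."""
    w = Fraction(value)
    if w < 0:
        raise ValidationError(f"weights must be non-negative, got {value!r}")
    return w


def vertex_id(compound_id: str, organism: str) -> str:
    """Stable vertex key: ``compound@organism``."""
    return f"{compound_id}@{organism}"


@dataclass(frozen=True)
class Vertex:
    """A compound inside one organism of the candidate consortium."""

    id: str
    compound_id: str
    organism: str

    @classmethod
    def make(cls, compound_id: str, organism: str) -> "Vertex":
        return cls(vertex_id(compound_id, organism), compound_id, organism)


@dataclass(frozen=True)
class Hyperarc:
    """A single-product reaction step, insertion copy, or compound transfer.

    ``reaction_id`` groups sibling arcs produced by multi-product
    decomposition; siblings share sources, weight, category and organism.
    ``organism`` is an organism id for endogenous/insertion arcs and an
    ``(from, to)`` pair for transitions.
    """

    id: str
    reaction_id: str
    sources: frozenset[str]
    target: str
    weight: Fraction
    category: str
    organism: Union[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValidationError(f"hyperarc {self.id!r} has no sources")
        if self.weight < 0:
            raise ValidationError(f"hyperarc {self.id!r} has negative weight")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"hyperarc {self.id!r}: unknown category {self.category!r}"
            )
        if self.category == TRANSITION and len(self.sources) != 1:
            raise ValidationError(
                f"transition {self.id!r} must have exactly one source"
            )


def spreadness(a: Hyperarc) -> int:
    """Number of tentacles of ``a``; the arc is tentacular iff this is > 1."""
    return len(a.sources)


class Hypergraph:
    """Keyed collections of vertices and hyperarcs with validation."""

    def __init__(self) -> None:
        self.vertices: dict[str, Vertex] = {}
        self.hyperarcs: dict[str, Hyperarc] = {}

    # -- construction ------------------------------------------------------

    def add_vertex(self, v: Vertex) -> Vertex:
        existing = self.vertices.get(v.id)
        if existing is not None:
            if existing != v:
                raise ValidationError(f"conflicting redefinition of vertex {v.id!r}")
            return existing
        self.vertices[v.id] = v
        return v

    def ensure_vertex(self, compound_id: str, organism: str) -> Vertex:
        return self.add_vertex(Vertex.make(compound_id, organism))

    def add_arc(self, a: Hyperarc) -> Hyperarc:
        if a.id in self.hyperarcs:
            raise ValidationError(f"duplicate hyperarc id {a.id!r}")
        for vid in [*a.sources, a.target]:
            if vid not in self.vertices:
                raise ValidationError(
                    f"hyperarc {a.id!r} references unknown vertex {vid!r}"
                )
        if a.category == TRANSITION:
            (src,) = a.sources
            u, v = self.vertices[src], self.vertices[a.target]
            if u.compound_id != v.compound_id or u.organism == v.organism:
                raise ValidationError(
                    f"transition {a.id!r} must move one compound between two "
                    f"distinct organisms"
                )
        self.hyperarcs[a.id] = a
        return a

    def copy(self) -> "Hypergraph":
        h = Hypergraph()
        h.vertices = dict(self.vertices)
        h.hyperarcs = dict(self.hyperarcs)
        return h

    # -- queries -----------------------------------------------------------

    def tentacular_ids(self) -> list[str]:
        return sorted(
            aid for aid, a in self.hyperarcs.items() if spreadness(a) > 1
        )

    def targets_of(self, arc_ids: Iterable[str]) -> frozenset[str]:
        """tgt(A'): all vertices produced by the given arcs."""
        return frozenset(self.hyperarcs[i].target for i in self._check_ids(arc_ids))

    def _check_ids(self, arc_ids: Iterable[str]) -> list[str]:
        ids = list(arc_ids)
        unknown = [i for i in ids if i not in self.hyperarcs]
        if unknown:
            raise ValidationError(f"unknown hyperarc ids: {sorted(unknown)}")
        return ids

    def _check_vertices(self, vids: Iterable[str]) -> frozenset[str]:
        vs = frozenset(vids)
        unknown = vs - self.vertices.keys()
        if unknown:
            raise ValidationError(f"unknown vertex ids: {sorted(unknown)}")
        return vs


def total_spreadness(h: Hypergraph) -> int:
    """Sum of the number of sources over all tentacular hyperarcs of ``h``."""
    return sum(
        len(a.sources) for a in h.hyperarcs.values() if len(a.sources) > 1
    )


# ---------------------------------------------------------------------------
# Raw reactions and multi-product decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """A reaction as read from a network table or SBML: possibly reversible,
    possibly multi-product.  Stoichiometric coefficients are deliberately not
    represented — the model is purely topological."""

    reaction_id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    reversible: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrates", tuple(self.substrates))
        object.__setattr__(self, "products", tuple(self.products))


def split_reversible(reactions: Iterable[Reaction]) -> list[Reaction]:
    """Replace every reversible reaction by two directed ones.

    The two directions get suffix-tagged ids (``_fwd``/``_rev``) and each
    carries the full reaction weight downstream; the model is purely
    directional, so no other convention is meaningful.
    """
    out: list[Reaction] = []
    for r in reactions:
        if r.reversible:
            out.append(
                Reaction(r.reaction_id + "_fwd", r.substrates, r.products)
            )
            out.append(
                Reaction(r.reaction_id + "_rev", r.products, r.substrates)
            )
        else:
            out.append(r)
    return out


@dataclass(frozen=True)
class DirectedReaction:
    """A decomposed reaction step: full substrate set, single product."""

    reaction_id: str
    sources: tuple[str, ...]
    target: str


def decompose_reactions(reactions: Iterable[Reaction]) -> list[DirectedReaction]:
    """Split reversible reactions, then decompose multi-product reactions
    into sibling steps that keep the whole substrate set and exactly one
    product each.  This loses no information: a reaction producing several
    compounds is usable per-product."""
    out: list[DirectedReaction] = []
    for r in split_reversible(reactions):
        if not r.substrates:
            raise ValidationError(
                f"reaction {r.reaction_id!r} has an empty substrate list"
            )
        if not r.products:
            raise ValidationError(
                f"reaction {r.reaction_id!r} has an empty product list"
            )
        for p in r.products:
            out.append(DirectedReaction(r.reaction_id, r.substrates, p))
    return out


def decompose_multi_target(
    reactions: Iterable[Reaction],
    organism: str,
    weight: WeightLike = 1,
    category: str = ENDOGENOUS,
) -> Hypergraph:
    """Build one organism's hypergraph from raw reactions.

    Every produced hyperarc has exactly one target; sibling arcs originating
    from one reaction share its ``reaction_id`` and weight.
    """
    w = as_weight(weight)
    h = Hypergraph()
    for step in decompose_reactions(reactions):
        srcs = frozenset(
            h.ensure_vertex(c, organism).id for c in step.sources
        )
        tgt = h.ensure_vertex(step.target, organism).id
        aid = f"{step.reaction_id}>{step.target}@{organism}"
        h.add_arc(
            Hyperarc(aid, step.reaction_id, srcs, tgt, w, category, organism)
        )
    return h


# ---------------------------------------------------------------------------
# Closure, rootedness, weight accounting
# ---------------------------------------------------------------------------


def closure(
    h: Hypergraph, arc_ids: Iterable[str], start: Iterable[str]
) -> frozenset[str]:
    """Least fixpoint of firing: the compounds producible from ``start``
    using only the given arcs, each arc requiring all of its substrates.

    Independent of iteration order (the firing relation is monotone).
    """
    ids = h._check_ids(arc_ids)
    avail = set(h._check_vertices(start))
    pending = [h.hyperarcs[i] for i in sorted(ids)]
    changed = True
    while changed and pending:
        changed = False
        still = []
        for a in pending:
            if a.sources <= avail:
                if a.target not in avail:
                    avail.add(a.target)
                    changed = True
            else:
                still.append(a)
        pending = still
    return frozenset(avail)


def is_rooted(
    h: Hypergraph, arc_ids: Iterable[str], sources: Iterable[str]
) -> tuple[bool, Optional[list[str]]]:
    """Check Definition-3 rootedness of an arc set at ``sources``.

    True iff the arcs admit an ordering in which every arc's substrates are
    supplied by the sources or by earlier arcs' products.  The greedy
    schedule is complete — firing an enabled arc never disables another — so
    the check is a simple saturation loop; a witness ordering is returned
    when one exists.
    """
    ids = h._check_ids(arc_ids)
    avail = set(h._check_vertices(sources))
    remaining = {i: h.hyperarcs[i] for i in ids}
    ordering: list[str] = []
    progress = True
    while remaining and progress:
        progress = False
        for aid in sorted(remaining):
            a = remaining[aid]
            if a.sources <= avail:
                avail.add(a.target)
                ordering.append(aid)
                del remaining[aid]
                progress = True
    if remaining:
        return False, None
    return True, ordering


def solution_weight(
    h: Hypergraph, arc_ids: Iterable[str]
) -> tuple[Fraction, dict[str, int]]:
    """Total weight of an arc set and its per-category breakdown.

    The total is the plain per-arc sum.  The breakdown counts distinct
    reactions (``reaction_id`` within organism) per category, so sibling arcs
    of one decomposed multi-product reaction count as one reaction — the
    convention used when reporting solution compositions.  For single-product
    reactions the two views coincide.
    """
    ids = h._check_ids(arc_ids)
    total = Fraction(0)
    seen: dict[str, set] = {c: set() for c in CATEGORIES}
    for i in ids:
        a = h.hyperarcs[i]
        total += a.weight
        seen[a.category].add((a.reaction_id, a.organism))
    return total, {c: len(s) for c, s in seen.items()}


@dataclass(frozen=True)
class SolutionHypertree:
    """A rooted arc set produced by the solver, with its rootedness witness,
    exact total weight and per-category reaction counts."""

    arcs: frozenset[str]
    ordering: tuple[str, ...]
    total_weight: Fraction
    breakdown: Mapping[str, int] = field(hash=False)

    @classmethod
    def from_arcs(
        cls,
        h: Hypergraph,
        arc_ids: Iterable[str],
        sources: Iterable[str],
    ) -> "SolutionHypertree":
        arcs = frozenset(arc_ids)
        ok, ordering = is_rooted(h, arcs, sources)
        if not ok:
            raise ValidationError("arc set is not rooted at the given sources")
        total, breakdown = solution_weight(h, arcs)
        return cls(arcs, tuple(ordering or ()), total, breakdown)

    def key(self) -> tuple[str, ...]:
        """Canonical identity of the solution: its sorted arc ids."""
        return tuple(sorted(self.arcs))
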