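"""Exact solver for the Directed Steiner Hypertree (DSH) problem.

Given a consortium instance — hypergraph H, sources S, targets T — find a
minimum-weight arc set A' that is rooted at S (its arcs can be ordered so
each one's substrates are supplied by S or by earlier products) and produces
every target.  The solver is exact and fixed-parameter tractable in
|T| + total spreadness:

1. Enumerate every *ordered* subset M = (a_1 .. a_k) of tentacular
   hyperarcs (2^k·k! combinations), the order being the topological order in
   which they fire in a candidate solution.
2. For each M, the substrates of M become extra targets (T' = T ∪ src(M))
   and its products extra sources (S' = S ∪ tgt(M)), stratified into layers:
   a tree may feed a target only from a source produced in a strictly lower
   layer.  The cheapest forest covering T' is then computed by a subset
   dynamic program over Y ⊆ T':

       SH_M(Y) = min( min_{s ∈ S_Y} ST(s, Y),
                      min_{∅ ⊂ Y' ⊂ Y} SH_M(Y') + SH_M(Y \\ Y') )

   where S_Y = {s ∈ S' : Layer_S(s) < Layer_T(Y)} and ST is the directed
   Steiner tree on the tentacular-free graph.
3. The optimum is min over M of weight(M) + SH_M(T').  Witnesses are
   rebuilt by interleaving forest arcs between the tentacular arcs per
   layer, then pruned to inclusion-minimality and validated.

Enumeration mode backtracks over every co-optimal combination, subset split,
root and Steiner witness, and deduplicates minimalized arc sets, yielding
the complete set of distinct optimal solutions (validated against the
brute-force oracle on small instances).

Targets that are also sources are, by default, still required to be
*produced* by some arc (strict reading of "T ⊆ tgt(A')"); the instance is
internally rewritten so the source role of such a compound is played by a
shadow vertex.  ``allow_source_targets=True`` instead grants them for free.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional

from .builder import ConsortiumInstance
from .errors import GuardrailError, ValidationError
from .hypergraph import (
    Hypergraph,
    SolutionHypertree,
    Vertex,
    closure,
    is_rooted,
    spreadness,
)
from .steiner import INF, ArcGraph, SteinerDP, Weight, arc_graph

MAX_TENTACULAR = 8
MAX_TERMINALS = 12


@dataclass(frozen=True)
class OrderedCombination:
    """An ordered subset M of tentacular arcs with its derived layer tables."""

    arcs: tuple[str, ...]
    T_prime: frozenset[str]
    S_prime: frozenset[str]
    layer_T: dict[str, int] = field(hash=False)
    layer_S: dict[str, int] = field(hash=False)

    def layer_key(self) -> tuple:
        """Canonical key of the induced layer structure, used to share the
        forest-cover DP between orderings that induce identical layers."""
        return (
            tuple(sorted(self.layer_T.items())),
            tuple(sorted(self.layer_S.items())),
        )


@dataclass(frozen=True)
class ForestCover:
    """A witness forest: per-tree (root, covered targets, edge ids)."""

    trees: tuple[tuple[str, frozenset[str], frozenset[str]], ...]
    covered: frozenset[str]

    def edge_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for _, _, edges in self.trees:
            out |= edges
        return frozenset(out)


@dataclass
class DshOutcome:
    """Solver result: optimal weight (None when infeasible), the distinct
    optimal solutions found, and the combination each one came from."""

    status: str  # "optimal" | "infeasible"
    optimal_weight: Optional[Fraction]
    solutions: list[SolutionHypertree]
    combinations_used: list[tuple[str, ...]]
    truncated: bool = False

    @property
    def feasible(self) -> bool:
        return self.status == "optimal"


# ---------------------------------------------------------------------------
# Combinations and layers
# ---------------------------------------------------------------------------


def enumerate_ordered_subsets(
    tentacular_ids: Sequence[str],
    max_k: Optional[int] = None,
    hard_limit: int = MAX_TENTACULAR,
    override_guardrail: bool = False,
) -> Iterator[tuple[str, ...]]:
    """Yield every ordered sequence of distinct tentacular ids, by length
    then lexicographically, each exactly once.  With k arcs this is
    sum_i k!/(k-i)! sequences, within the 2^k·k! bound."""
    ids = sorted(set(tentacular_ids))
    k = len(ids)
    if k > hard_limit and not override_guardrail:
        raise GuardrailError(
            f"{k} tentacular hyperarcs exceeds the guardrail of {hard_limit}; "
            f"pass an explicit override to enumerate 2^k·k! orderings anyway"
        )
    top = k if max_k is None else min(k, max_k)
    for length in range(top + 1):
        yield from itertools.permutations(ids, length)


def compute_layers(
    m: Sequence[str],
    sources: Iterable[str],
    targets: Iterable[str],
    h: Hypergraph,
) -> OrderedCombination:
    """Derive T', S' and the layer tables for an ordered combination.

    Layer_T(t) is the first position whose tentacular arc consumes t (k+1
    for plain targets); Layer_S(s) is 0 on S — sources take precedence —
    else the first position producing s.
    """
    k = len(m)
    for aid in m:
        a = h.hyperarcs.get(aid)
        if a is None:
            raise ValidationError(f"unknown hyperarc {aid!r} in combination")
        if spreadness(a) <= 1:
            raise ValidationError(f"hyperarc {aid!r} is not tentacular")
    S = frozenset(sources)
    T = frozenset(targets)
    layer_T: dict[str, int] = {t: k + 1 for t in T}
    layer_S: dict[str, int] = {s: 0 for s in S}
    for pos, aid in enumerate(m, start=1):
        a = h.hyperarcs[aid]
        for src in a.sources:
            if layer_T.get(src, k + 2) > pos:
                layer_T[src] = pos
        if a.target not in layer_S:
            layer_S[a.target] = pos
    return OrderedCombination(
        arcs=tuple(m),
        T_prime=frozenset(layer_T),
        S_prime=frozenset(layer_S),
        layer_T=layer_T,
        layer_S=layer_S,
    )


def candidate_roots(comb: OrderedCombination, Y: Iterable[str]) -> frozenset[str]:
    """S_Y: the sources usable as tree roots for the target subset Y —
    those whose layer precedes every layer of Y."""
    ys = frozenset(Y)
    if not ys:
        raise ValidationError("Y must be non-empty")
    unknown = ys - comb.T_prime
    if unknown:
        raise ValidationError(f"targets outside T': {sorted(unknown)}")
    layer_y = min(comb.layer_T[t] for t in ys)
    return frozenset(
        s for s, l in comb.layer_S.items() if l < layer_y
    )


# ---------------------------------------------------------------------------
# Forest-cover DP (SH_M)
# ---------------------------------------------------------------------------


class _ForestDP:
    """Memoized SH_M recursion over subsets of T' for one layer structure."""

    def __init__(self, dp: SteinerDP, comb: OrderedCombination):
        self.dp = dp
        self.comb = comb
        self.terminals = dp.terminals  # sorted T'
        self._value: dict[int, Weight] = {}

    def roots_for_mask(self, mask: int) -> list[str]:
        ys = [self.terminals[i] for i in range(len(self.terminals)) if mask >> i & 1]
        return sorted(candidate_roots(self.comb, ys))

    def value(self, mask: int) -> Weight:
        if mask in self._value:
            return self._value[mask]
        best: Weight = INF
        for s in self.roots_for_mask(mask):
            w = self.dp.value(s, self._subset(mask))
            if w < best:
                best = w
        sub = (mask - 1) & mask
        low = mask & -mask
        while sub:
            if sub & low:
                a = self.value(sub)
                b = self.value(mask ^ sub)
                if a != INF and b != INF and a + b < best:
                    best = a + b
            sub = (sub - 1) & mask
        self._value[mask] = best
        return best

    def _subset(self, mask: int) -> list[str]:
        return [t for i, t in enumerate(self.terminals) if mask >> i & 1]

    # -- witnesses ---------------------------------------------------------

    def forests(self, mask: int) -> Iterator[ForestCover]:
        """All co-optimal forests for the subset, as (root, Y, edges) trees."""
        target = self.value(mask)
        if target == INF:
            return
        seen: set[frozenset] = set()
        order = lambda t: (t[0], tuple(sorted(t[1])), tuple(sorted(t[2])))
        for trees in self._realize(mask, target):
            cover = ForestCover(
                trees=tuple(sorted(trees, key=order)),
                covered=frozenset(self._subset(mask)),
            )
            key = frozenset(trees)
            if key not in seen:
                seen.add(key)
                yield cover

    def forest(self, mask: int) -> Optional[ForestCover]:
        for f in self.forests(mask):
            return f
        return None

    def _realize(
        self, mask: int, target: Weight
    ) -> Iterator[list[tuple[str, frozenset[str], frozenset[str]]]]:
        ys = frozenset(self._subset(mask))
        for s in self.roots_for_mask(mask):
            if self.dp.value(s, ys) == target:
                for tree in self.dp.trees(s, ys):
                    yield [(s, ys, tree)]
        sub = (mask - 1) & mask
        low = mask & -mask
        while sub:
            if sub & low:
                a = self.value(sub)
                b = self.value(mask ^ sub)
                if a != INF and b != INF and a + b == target:
                    for left in self._realize(sub, a):
                        for right in self._realize(mask ^ sub, b):
                            yield left + right
            sub = (sub - 1) & mask


def solve_SH(
    g: ArcGraph, comb: OrderedCombination
) -> tuple[Weight, Optional[ForestCover]]:
    """Minimum weight of a forest covering T' under the combination's layer
    constraints, with one witness forest (None when no cover exists)."""
    dp = SteinerDP(g, comb.T_prime)
    fdp = _ForestDP(dp, comb)
    full = (1 << len(dp.terminals)) - 1
    w = fdp.value(full)
    if w == INF:
        return INF, None
    return w, fdp.forest(full)


# ---------------------------------------------------------------------------
# Strict handling of targets that are also sources
# ---------------------------------------------------------------------------


def _split_source_targets(
    h: Hypergraph, S: frozenset[str], T: frozenset[str]
) -> tuple[Hypergraph, frozenset[str]]:
    """Rewrite the instance so a compound that is both a source and a target
    keeps its target role while its source role moves to a shadow vertex.

    Arcs consuming such a compound consume the shadow instead (it is
    available from the start, exactly as the original was), while the
    compound itself must still be produced.  Arc ids are unchanged, so
    solutions translate back one-to-one.
    """
    both = S & T
    if not both:
        return h, S
    new_h = Hypergraph()
    shadow = {v: f"{v}#src" for v in both}
    for v in h.vertices.values():
        new_h.add_vertex(v)
    for vid, sid in shadow.items():
        v = h.vertices[vid]
        new_h.add_vertex(Vertex(sid, v.compound_id, v.organism))
    for aid in sorted(h.hyperarcs):
        a = h.hyperarcs[aid]
        srcs = frozenset(shadow.get(s, s) for s in a.sources)
        if srcs != a.sources:
            a = replace(a, sources=srcs)
        new_h.hyperarcs[a.id] = a
    new_S = frozenset(shadow.get(s, s) for s in S)
    return new_h, new_S


# ---------------------------------------------------------------------------
# Top-level solve
# ---------------------------------------------------------------------------


def _minimalize(
    h: Hypergraph,
    arcs: frozenset[str],
    S: frozenset[str],
    required: frozenset[str],
) -> frozenset[str]:
    """Remove arcs whose deletion preserves rootedness and target coverage,
    scanning in lexicographic id order to a fixpoint (deterministic)."""
    current = set(arcs)
    changed = True
    while changed:
        changed = False
        for aid in sorted(current):
            trial = current - {aid}
            if not required <= h.targets_of(trial):
                continue
            ok, _ = is_rooted(h, trial, S)
            if ok:
                current = trial
                changed = True
    return frozenset(current)


def _plain_part_is_forest(
    h: Hypergraph, arcs: frozenset[str], S_prime: frozenset[str]
) -> bool:
    """Structural sanity of a minimalized solution: its single-source part
    is a forest (every vertex has at most one incoming plain arc)."""
    indeg: dict[str, int] = {}
    for aid in arcs:
        a = h.hyperarcs[aid]
        if spreadness(a) == 1:
            indeg[a.target] = indeg.get(a.target, 0) + 1
    return all(c <= 1 for c in indeg.values())


class _Solver:
    def __init__(
        self,
        instance: ConsortiumInstance,
        allow_source_targets: bool = False,
        max_tentacular: int = MAX_TENTACULAR,
        max_terminals: int = MAX_TERMINALS,
        override_guardrails: bool = False,
    ):
        instance.validate()
        self.instance = instance
        self.allow_source_targets = allow_source_targets
        self.max_tentacular = max_tentacular
        self.max_terminals = max_terminals
        self.override = override_guardrails

        self.h_orig = instance.hypergraph
        if allow_source_targets:
            self.T = frozenset(instance.T - instance.S)
            self.h, self.S = self.h_orig, frozenset(instance.S)
        else:
            self.T = frozenset(instance.T)
            self.h, self.S = _split_source_targets(
                self.h_orig, frozenset(instance.S), self.T
            )
        self.g = arc_graph(self.h)
        self.producible = closure(self.h, self.h.hyperarcs.keys(), self.S)
        self.tentacular = [
            aid
            for aid in self.h.tentacular_ids()
            if self.h.hyperarcs[aid].sources <= self.producible
        ]
        self._sh_cache: dict[tuple, tuple[Weight, "_ForestDP", int]] = {}
        self._steiner_cache: dict[frozenset, SteinerDP] = {}

    # -- plumbing ----------------------------------------------------------

    def _weight_of(self, arcs: Iterable[str]) -> Fraction:
        return sum(
            (self.h.hyperarcs[a].weight for a in arcs), Fraction(0)
        )

    def _forest_dp(self, comb: OrderedCombination) -> tuple[Weight, "_ForestDP", int]:
        key = comb.layer_key()
        hit = self._sh_cache.get(key)
        if hit is not None:
            return hit
        tkey = comb.T_prime
        dp = self._steiner_cache.get(tkey)
        if dp is None:
            dp = SteinerDP(self.g, comb.T_prime)
            self._steiner_cache[tkey] = dp
        fdp = _ForestDP(dp, comb)
        full = (1 << len(dp.terminals)) - 1
        value = fdp.value(full)
        out = (value, fdp, full)
        self._sh_cache[key] = out
        return out

    def _combinations(self) -> Iterator[OrderedCombination]:
        for m in enumerate_ordered_subsets(
            self.tentacular,
            hard_limit=self.max_tentacular,
            override_guardrail=self.override,
        ):
            comb = compute_layers(m, self.S, self.T, self.h)
            if len(comb.T_prime) > self.max_terminals:
                if not self.override:
                    raise GuardrailError(
                        f"|T'| = {len(comb.T_prime)} exceeds the guardrail of "
                        f"{self.max_terminals}; pass an explicit override"
                    )
            yield comb

    # -- search ------------------------------------------------------------

    def best_weight(self) -> tuple[Weight, list[OrderedCombination]]:
        """Optimum over all combinations; also returns the co-optimal ones."""
        if not self.T:
            return Fraction(0), []
        if not self.T <= self.producible:
            return INF, []
        best: Weight = INF
        winners: list[OrderedCombination] = []
        for comb in self._combinations():
            value, _, _ = self._forest_dp(comb)
            if value == INF:
                continue
            total = value + self._weight_of(comb.arcs)
            if total < best:
                best = total
                winners = [comb]
            elif total == best:
                winners.append(comb)
        return best, winners

    def _assemble(
        self, comb: OrderedCombination, forest: ForestCover
    ) -> Optional[SolutionHypertree]:
        """Interleave forest arcs with the tentacular arcs (the layer
        construction guarantees a valid firing order), minimalize, validate
        against the *original* instance and rebuild the witness there."""
        arcs = frozenset(comb.arcs) | forest.edge_ids()
        required = self.T
        arcs = _minimalize(self.h, arcs, self.S, required)
        ok, _ = is_rooted(self.h, arcs, self.S)
        if not ok or not required <= self.h.targets_of(arcs):
            return None
        if not _plain_part_is_forest(self.h, arcs, comb.S_prime):
            return None
        # translate to the original hypergraph (ids are shared)
        return SolutionHypertree.from_arcs(self.h_orig, arcs, self.instance.S)

    def solve(self) -> DshOutcome:
        best, winners = self.best_weight()
        if not self.T:
            empty = SolutionHypertree.from_arcs(self.h_orig, (), self.instance.S)
            return DshOutcome("optimal", Fraction(0), [empty], [()])
        if best == INF:
            return DshOutcome("infeasible", None, [], [])
        for comb in winners:
            _, fdp, full = self._forest_dp(comb)
            forest = fdp.forest(full)
            if forest is None:
                continue
            sol = self._assemble(comb, forest)
            if sol is not None:
                if sol.total_weight != best:
                    raise AssertionError(
                        "witness weight disagrees with the DP optimum"
                    )
                return DshOutcome("optimal", best, [sol], [comb.arcs])
        raise AssertionError("no witness could be reconstructed at the optimum")

    def enumerate(self, cap: int = 1000) -> DshOutcome:
        if cap < 1:
            raise ValidationError("cap must be >= 1")
        best, winners = self.best_weight()
        if not self.T:
            empty = SolutionHypertree.from_arcs(self.h_orig, (), self.instance.S)
            return DshOutcome("optimal", Fraction(0), [empty], [()])
        if best == INF:
            return DshOutcome("infeasible", None, [], [])
        found: dict[tuple[str, ...], SolutionHypertree] = {}
        combo_of: dict[tuple[str, ...], tuple[str, ...]] = {}
        truncated = False
        for comb in winners:
            _, fdp, full = self._forest_dp(comb)
            for forest in fdp.forests(full):
                sol = self._assemble(comb, forest)
                if sol is None or sol.total_weight != best:
                    continue
                key = sol.key()
                if key not in found:
                    found[key] = sol
                    combo_of[key] = comb.arcs
                    if len(found) > cap:
                        truncated = True
                        break
            if truncated:
                break
        keys = sorted(found)[:cap]
        return DshOutcome(
            "optimal",
            best,
            [found[k] for k in keys],
            [combo_of[k] for k in keys],
            truncated=truncated,
        )


def solve_dsh(
    instance: ConsortiumInstance,
    allow_source_targets: bool = False,
    max_tentacular: int = MAX_TENTACULAR,
    max_terminals: int = MAX_TERMINALS,
    override_guardrails: bool = False,
) -> DshOutcome:
    """Solve the instance exactly; returns the optimal weight and one
    witness solution (or an infeasible outcome, never an exception for
    plain infeasibility)."""
    return _Solver(
        instance,
        allow_source_targets,
        max_tentacular,
        max_terminals,
        override_guardrails,
    ).solve()


def enumerate_optimal(
    instance: ConsortiumInstance,
    cap: int = 1000,
    allow_source_targets: bool = False,
    max_tentacular: int = MAX_TENTACULAR,
    max_terminals: int = MAX_TERMINALS,
    override_guardrails: bool = False,
) -> DshOutcome:
    """All distinct optimal solutions (inclusion-minimal arc sets), up to
    ``cap``; ``truncated`` reports whether the cap cut the enumeration."""
    return _Solver(
        instance,
        allow_source_targets,
        max_tentacular,
        max_terminals,
        override_guardrails,
    ).enumerate(cap)
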