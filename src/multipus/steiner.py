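"""Minimum-weight directed Steiner arborescences on the tentacular-free graph.

Removing every tentacular hyperarc from the instance leaves an ordinary
directed multigraph (transitions, insertions and single-substrate reactions
are all plain arcs).  On that graph, ``ST(x, X)`` — the cheapest arborescence
rooted at ``x`` whose leaves all lie in the terminal set ``X`` and that
contains all of ``X`` — is computed by the Dreyfus–Wagner subset dynamic
program, exponential only in ``|X|``:

    path(v, D)  = min over u of  dist(v, u) + merge(u, D)
    merge(u, D) = min over nonempty proper D' ⊂ D of  path(u, D') + path(u, D\\D')
    path(v,{t}) = dist(v, t)

Every optimal tree decomposes this way at its branch vertices and internal
terminals, and between those key vertices an optimal tree always follows a
shortest path, so backtracking over all co-optimal choices (including all
co-optimal shortest paths) enumerates every optimal tree — a property the
enumeration mode of the consortium solver relies on.

Parallel arcs are first-class: two equal-weight arcs between the same pair
of vertices are two distinct solutions.  The ``∞`` sentinel is
``math.inf``, never a large finite number.
"""

from __future__ import annotations

import heapq
import math
from collections.abc import Iterable, Iterator
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Union

from .errors import ValidationError
from .hypergraph import Hypergraph, spreadness

INF = math.inf
Weight = Union[Fraction, float]  # Fraction, or math.inf when unreachable


@dataclass(frozen=True)
class Edge:
    id: str
    u: str
    v: str
    weight: Fraction


class ArcGraph:
    """The instance's single-source arcs as a weighted directed multigraph."""

    def __init__(self, vertices: Iterable[str] = (), edges: Iterable[Edge] = ()):
        self.vertices: set[str] = set(vertices)
        self.edges: dict[str, Edge] = {}
        self._out: dict[str, list[Edge]] = {}
        self._in: dict[str, list[Edge]] = {}
        for e in edges:
            self.add_edge(e)

    def add_edge(self, e: Edge) -> None:
        if e.id in self.edges:
            raise ValidationError(f"duplicate edge id {e.id!r}")
        if e.u not in self.vertices or e.v not in self.vertices:
            raise ValidationError(f"edge {e.id!r} references unknown vertex")
        self.edges[e.id] = e
        self._out.setdefault(e.u, []).append(e)
        self._in.setdefault(e.v, []).append(e)

    def out_edges(self, v: str) -> list[Edge]:
        return self._out.get(v, [])

    def in_edges(self, v: str) -> list[Edge]:
        return self._in.get(v, [])


def arc_graph(h: Hypergraph) -> ArcGraph:
    """Drop every tentacular hyperarc; keep ids and weights of the rest."""
    g = ArcGraph(h.vertices.keys())
    for aid in sorted(h.hyperarcs):
        a = h.hyperarcs[aid]
        if spreadness(a) == 1:
            (src,) = a.sources
            g.add_edge(Edge(aid, src, a.target, a.weight))
    return g


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------


def _dijkstra(g: ArcGraph, source: str, reverse: bool = False) -> dict[str, Weight]:
    """Single-source distances; follows arcs backwards when ``reverse``."""
    dist: dict[str, Weight] = {source: Fraction(0)}
    heap: list[tuple[Weight, str]] = [(Fraction(0), source)]
    done: set[str] = set()
    while heap:
        d, v = heapq.heappop(heap)
        if v in done:
            continue
        done.add(v)
        for e in g.in_edges(v) if reverse else g.out_edges(v):
            w = e.u if reverse else e.v
            nd = d + e.weight
            if nd < dist.get(w, INF):
                dist[w] = nd
                heapq.heappush(heap, (nd, w))
    return dist


class _DistCache:
    def __init__(self, g: ArcGraph):
        self.g = g
        self._fwd: dict[str, dict[str, Weight]] = {}
        self._rev: dict[str, dict[str, Weight]] = {}

    def from_(self, u: str) -> dict[str, Weight]:
        if u not in self._fwd:
            self._fwd[u] = _dijkstra(self.g, u)
        return self._fwd[u]

    def to(self, v: str) -> dict[str, Weight]:
        if v not in self._rev:
            self._rev[v] = _dijkstra(self.g, v, reverse=True)
        return self._rev[v]

    def dist(self, u: str, v: str) -> Weight:
        return self.from_(u).get(v, INF)


def shortest_path(g: ArcGraph, u: str, v: str) -> tuple[Weight, list[str]]:
    """Minimum-weight directed path as (weight, edge-id list).

    ``(0, [])`` when ``u == v``; ``(inf, [])`` when unreachable.  Among
    co-optimal paths the lexicographically smallest edge-id sequence is
    returned, so the result is deterministic.
    """
    if u not in g.vertices or v not in g.vertices:
        raise ValidationError(f"unknown vertex in shortest_path({u!r}, {v!r})")
    cache = _DistCache(g)
    total = cache.dist(u, v)
    if total == INF:
        return INF, []
    for path in _all_shortest_paths(g, cache, u, v):
        return total, path  # generator yields in lexicographic edge-id order
    raise AssertionError("unreachable")


def _all_shortest_paths(
    g: ArcGraph, cache: _DistCache, u: str, v: str
) -> Iterator[list[str]]:
    """All simple shortest u→v paths, as edge-id lists, lexicographically.

    An edge (a, b) lies on a shortest path iff
    ``dist(u,a) + w + dist(b,v) == dist(u,v)``; zero-weight cycles are cut
    off by keeping paths simple (an optimal tree never repeats a vertex).
    """
    dv = cache.from_(u)
    rv = cache.to(v)
    total = dv.get(v, INF)
    if total == INF:
        return

    def walk(a: str, used: Fraction, visited: frozenset[str]) -> Iterator[list[str]]:
        if a == v and used == total:
            yield []
            return
        cand = [
            e
            for e in g.out_edges(a)
            if e.v not in visited
            and used + e.weight + rv.get(e.v, INF) == total
        ]
        for e in sorted(cand, key=lambda e: e.id):
            for tail in walk(e.v, used + e.weight, visited | {e.v}):
                yield [e.id, *tail]

    yield from walk(u, Fraction(0), frozenset({u}))


# ---------------------------------------------------------------------------
# Steiner subset DP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteinerResult:
    """One optimal arborescence: arcs oriented away from ``root``, every
    terminal in the tree, every leaf a terminal."""

    root: str
    terminals: frozenset[str]
    weight: Weight
    arcs: frozenset[str]


class SteinerDP:
    """Dreyfus–Wagner tables for one terminal universe.

    The tables ``path[mask][v]`` are root-independent, so one instance
    serves every (root, terminal-subset) query over the same universe —
    exactly what the forest-cover recursion of the consortium solver needs.
    Subsets are bitmasks over the terminal list in sorted-id order.
    """

    def __init__(self, g: ArcGraph, terminals: Iterable[str]):
        self.g = g
        self.terminals: tuple[str, ...] = tuple(sorted(set(terminals)))
        if not self.terminals:
            raise ValidationError("terminal set must be non-empty")
        unknown = [t for t in self.terminals if t not in g.vertices]
        if unknown:
            raise ValidationError(f"unknown terminals: {unknown}")
        self.index = {t: i for i, t in enumerate(self.terminals)}
        self.cache = _DistCache(g)
        self._path: dict[int, dict[str, Weight]] = {}
        self._merge: dict[int, dict[str, Weight]] = {}

    def mask_of(self, subset: Iterable[str]) -> int:
        m = 0
        for t in subset:
            m |= 1 << self.index[t]
        return m

    def _tables(self, mask: int) -> tuple[dict[str, Weight], dict[str, Weight]]:
        if mask in self._path:
            return self._path[mask], self._merge[mask]
        if mask == 0 or mask & ~((1 << len(self.terminals)) - 1):
            raise ValidationError("invalid terminal mask")
        verts = sorted(self.g.vertices)
        if mask & (mask - 1) == 0:
            t = self.terminals[mask.bit_length() - 1]
            rv = self.cache.to(t)
            path = {v: rv.get(v, INF) for v in verts}
            merge = {v: (Fraction(0) if v == t else INF) for v in verts}
        else:
            merge = {}
            for v in verts:
                best: Weight = INF
                sub = (mask - 1) & mask
                low = mask & -mask
                while sub:
                    if sub & low:  # canonical halves: keep lowest bit on one side
                        a = self._tables(sub)[0][v]
                        b = self._tables(mask ^ sub)[0][v]
                        if a != INF and b != INF and a + b < best:
                            best = a + b
                    sub = (sub - 1) & mask
                merge[v] = best
            # relax by shortest paths: one Dijkstra over the reverse graph
            # seeded with the merge values
            path = dict(merge)
            heap = [(w, v) for v, w in path.items() if w != INF]
            heapq.heapify(heap)
            done: set[str] = set()
            while heap:
                d, v = heapq.heappop(heap)
                if v in done:
                    continue
                done.add(v)
                for e in self.g.in_edges(v):
                    nd = d + e.weight
                    if nd < path.get(e.u, INF):
                        path[e.u] = nd
                        heapq.heappush(heap, (nd, e.u))
        self._path[mask] = path
        self._merge[mask] = merge
        return path, merge

    def value(self, root: str, subset: Iterable[str]) -> Weight:
        """Weight of the cheapest arborescence from ``root`` spanning the
        subset (``inf`` when some terminal is unreachable)."""
        mask = self.mask_of(subset)
        return self._tables(mask)[0][root]

    # -- reconstruction ----------------------------------------------------

    def trees(self, root: str, subset: Iterable[str]) -> Iterator[frozenset[str]]:
        """Enumerate every optimal arborescence as a frozenset of edge ids,
        deduplicated, in a deterministic order."""
        mask = self.mask_of(subset)
        if self._tables(mask)[0][root] == INF:
            return
        seen: set[frozenset[str]] = set()
        for arcs in self._realize_path(root, mask):
            tree = frozenset(arcs)
            if tree not in seen:
                seen.add(tree)
                yield tree

    def tree(self, root: str, subset: Iterable[str]) -> Optional[frozenset[str]]:
        """One optimal arborescence (deterministic tie-break), or None."""
        for t in self.trees(root, subset):
            return t
        return None

    def _realize_path(self, v: str, mask: int) -> Iterator[list[str]]:
        path_tab, merge_tab = self._tables(mask)
        target = path_tab[v]
        if target == INF:
            return
        # terminal-path base for singletons is subsumed: merge at the terminal
        for u in sorted(self.g.vertices):
            mu = merge_tab[u]
            if mu == INF:
                continue
            d = self.cache.dist(v, u)
            if d == INF or d + mu != target:
                continue
            for p in _all_shortest_paths(self.g, self.cache, v, u):
                for rest in self._realize_merge(u, mask):
                    yield p + rest

    def _realize_merge(self, v: str, mask: int) -> Iterator[list[str]]:
        path_tab, merge_tab = self._tables(mask)
        target = merge_tab[v]
        if target == INF:
            return
        if mask & (mask - 1) == 0:
            if target == 0:
                yield []
            return
        low = mask & -mask
        sub = (mask - 1) & mask
        splits = []
        while sub:
            if sub & low:
                a = self._tables(sub)[0][v]
                b = self._tables(mask ^ sub)[0][v]
                if a != INF and b != INF and a + b == target:
                    splits.append(sub)
            sub = (sub - 1) & mask
        for s in sorted(splits):
            for left in self._realize_path(v, s):
                for right in self._realize_path(v, mask ^ s):
                    yield left + right


def _extract_tree(
    g: ArcGraph, root: str, terminals: frozenset[str], edge_ids: Iterable[str]
) -> frozenset[str]:
    """Prune an optimal edge multiset union down to a clean arborescence:
    in-degree ≤ 1 everywhere, all edges on root→terminal paths, every leaf a
    terminal.  With non-negative weights pruning never increases weight."""
    # a minimal arborescence never re-enters its root
    edges = {
        eid: g.edges[eid] for eid in set(edge_ids) if g.edges[eid].v != root
    }
    while True:
        # keep only edges forward-reachable from root and backward-useful
        reach = {root}
        frontier = [root]
        out: dict[str, list[Edge]] = {}
        inc: dict[str, list[Edge]] = {}
        for e in edges.values():
            out.setdefault(e.u, []).append(e)
            inc.setdefault(e.v, []).append(e)
        while frontier:
            v = frontier.pop()
            for e in out.get(v, []):
                if e.v not in reach:
                    reach.add(e.v)
                    frontier.append(e.v)
        useful = set(t for t in terminals if t in reach)
        changed = True
        while changed:
            changed = False
            for e in edges.values():
                if e.v in useful and e.u in reach and e.u not in useful:
                    useful.add(e.u)
                    changed = True
        pruned = {
            eid: e
            for eid, e in edges.items()
            if e.u in reach and e.v in useful and e.u in useful
        }
        if len(pruned) != len(edges):
            edges = pruned
            continue
        # resolve an in-degree >= 2 vertex: keep one incoming edge whose tail
        # is reachable from the root without passing through the vertex (so
        # no cycle is kept), lexicographically smallest among those
        dup = None
        for v in sorted({e.v for e in edges.values()}):
            ins = sorted(eid for eid, e in edges.items() if e.v == v)
            if len(ins) <= 1:
                continue
            safe = {root}
            frontier = [root]
            while frontier:
                x = frontier.pop()
                for e in edges.values():
                    if e.u == x and e.v not in safe and e.v != v:
                        safe.add(e.v)
                        frontier.append(e.v)
            keep = next(
                eid for eid in ins if edges[eid].u in safe
            )  # exists: v is reachable via some simple path from the root
            dup = [eid for eid in ins if eid != keep]
            break
        if dup is None:
            return frozenset(edges)
        for eid in dup:
            del edges[eid]


def steiner_tree(
    g: ArcGraph, root: str, terminals: Iterable[str]
) -> SteinerResult:
    """Best directed Steiner tree rooted at ``root`` containing all
    ``terminals``; ``weight`` is ``inf`` (with empty arcs) when some terminal
    is unreachable."""
    terms = frozenset(terminals)
    if not terms:
        raise ValidationError("terminal set must be non-empty")
    if root not in g.vertices:
        raise ValidationError(f"unknown root {root!r}")
    dp = SteinerDP(g, terms)
    w = dp.value(root, terms)
    if w == INF:
        return SteinerResult(root, terms, INF, frozenset())
    witness = dp.tree(root, terms)
    assert witness is not None
    arcs = _extract_tree(g, root, terms, witness)
    total = sum((g.edges[e].weight for e in arcs), Fraction(0))
    assert total == w, "witness weight disagrees with the DP optimum"
    return SteinerResult(root, terms, w, arcs)
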