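# Methods

## The model and its assumptions

A consortium-design instance is a weighted directed hypergraph over
vertices `(compound, organism)`. Reactions are hyperarcs from a substrate
set to a single product; multi-product reactions are decomposed into
sibling arcs (same substrates, same `reaction_id`, one product each), which
loses no information because a reaction is usable per product. Reversible
reactions are split into two directed reactions with suffix-tagged ids
(`_fwd`/`_rev`), each carrying the full weight: the model is purely
directional, so no other convention is meaningful.

The model is topological. It deliberately ignores stoichiometric
coefficients, cofactor balancing (ubiquitous cofactors are instead removed
up front from a user-supplied list), thermodynamics, flux, growth and
regulation. A design found here is a parsimonious reaction/transport/
insertion set, to be vetted afterwards by flux-based methods and by
checking that the proposed transports have plausible transporters.

Compound identity across organisms and with reference networks is exact
string equality of compound ids (KEGG-style identifiers assumed
pre-normalized); reaction identity for "already present in the worker" is
exact `reaction_id` equality on the directed, reversibility-split form.

### Costs

| parameter | meaning | default |
|---|---|---|
| `w_worker` | endogenous reaction in a worker | 1 |
| `w_other` | inserting a reference reaction into a worker | 100 |
| `w_transition` | moving one compound between two organisms | 100 |
| overrides | per-reaction or per-compound exceptions | — |

All weights are non-negative rationals (`fractions.Fraction`); totals are
compared exactly, with no floating tolerance, which keeps "all optimal
solutions" well defined. The defaults encode the prior that transport and
heterologous expression are roughly equally painful and both two orders of
magnitude worse than using chemistry an organism already has; `w_worker` is
1 rather than 0 so that, among designs with equally many insertions and
transports, the one with fewest internal reactions wins. Setting
`w_worker = 0` is legal; inclusion-minimal pruning of reported solutions
prevents zero-weight padding arcs from appearing.

A target that is also a source must still be *produced* by default (strict
reading of "T ⊆ tgt(A′)"); this is implemented by an exact rewrite that
moves the compound's source role to a shadow vertex, so arc ids and
solutions are unchanged. `allow_source_targets=True` grants such targets
for free instead.

## The solver

The solver enumerates ordered subsets `M` of tentacular (multi-substrate)
hyperarcs — the order is the topological firing order in a candidate
solution — and for each `M` computes the cheapest forest of plain arcs
covering `T′ = T ∪ src(M)` under layer constraints, by a memoized subset
recursion whose base case is the directed Steiner tree `ST(s, Y)` on the
tentacular-free graph. `ST` uses the Dreyfus–Wagner dynamic program over
(vertex, terminal-subset) states; subsets are bitmasks over the terminals
in sorted-id order, so every run is deterministic. Combinations whose
tentacular substrates lie outside the closure of the full arc set from `S`
are pruned (they can never fire); combinations inducing identical layer
tables share one forest-DP evaluation, and Steiner tables are shared per
terminal universe `T′` since they are root-independent.

Witness reconstruction interleaves forest arcs between the tentacular arcs
by layer, prunes arcs whose deletion preserves rootedness and coverage
(lexicographic scan to a fixpoint — deterministic), and validates the
result: rootedness witness, target coverage, forest structure of the plain
part, and exact agreement of the reconstructed weight with the DP optimum
are all checked at run time.

### Enumerating all optimal designs

Enumeration mode backtracks over every co-optimal ordered combination,
every co-optimal split/root choice in the forest recursion, every
co-optimal merge in the Steiner tables and every co-optimal shortest path
(simple paths only, which cuts zero-weight cycles). Each reconstructed arc
set is minimalized and deduplicated by its sorted arc-id set, with a
caller-supplied cap and a truncation flag. Two facts make this complete:
every inclusion-minimal optimal solution uses exactly the tentacular arcs
of some ordered combination, and within an optimal tree the path between
consecutive key vertices (root, branch points, terminals) is always a
shortest path — replacing a non-shortest segment would yield a strictly
cheaper feasible solution. Completeness is additionally verified
empirically: on a thousand seeded random instances the enumerated solution
sets equal the brute-force oracle's, as sets of arc sets
(`tests/test_acceptance.py`).

### Guardrails

The search is exponential in the number of tentacular arcs (`2^k·k!`
orderings) and in `|T′| ≤ |T| +` total spreadness. Defaults refuse more
than 8 tentacular arcs or `|T′| > 12` unless explicitly overridden. The
brute-force oracle refuses instances above 14 arcs (2^14 subsets) without
an explicit limit.

### Numerical and tie-breaking choices

* ∞ is `math.inf`, a distinguished sentinel — never a large finite weight.
* All iteration orders are fixed by sorted ids; the solver contains no
  randomness, so identical inputs give identical outputs, including DOT
  and JSON exports (byte-identical).
* Tie-breaks in single-witness mode pick the lexicographically smallest
  co-optimal choice (merge vertex, subset mask, edge id).
* Degenerate inputs: an empty effective target set yields the empty
  solution at weight 0; an unproducible target yields an explicit
  infeasible outcome (solver) or error (compression), not an exception
  from the middle of the DP.

## Lossless pre-solve compression

Three reductions, applied to a fixpoint, shrink genome-scale-shaped inputs
without changing the answer:

1. **forward pruning** — drop vertices outside `closure(A, S)` (never
   producible) and their arcs; if a target is dropped the instance is
   reported infeasible;
2. **backward pruning** — drop vertices from which no chain of "is a
   substrate of an arc producing something useful" reaches a target: an
   induction over the firing order shows no inclusion-minimal solution can
   contain an arc pointing outside this set;
3. **chain contraction** — splice out an unprotected vertex with exactly
   one incoming and one outgoing arc, both single-substrate endogenous
   arcs of the same organism and not touching any tentacular arc, merging
   the two arcs with summed weight. This is a bijection on solutions; an
   expansion map restores the original arcs (and the original weight,
   checked exactly) afterwards.

Rules 1–2 delete only arcs that no inclusion-minimal solution uses, so the
reduction preserves not just the optimal weight but the entire set of
minimal optimal solutions up to expansion — verified against the oracle on
mixed feasible/infeasible instances. Contraction is deliberately
restricted to same-organism endogenous pairs so merged arcs keep a
meaningful category; this is conservative (it may leave some contractible
transitions in place) but keeps reported breakdowns interpretable.

## Synthetic data

### Random instances

`GeneratorParams` defaults describe the regime in which the brute-force
oracle is usable as ground truth: two organisms drawing four compounds
each from a seven-compound shared pool (so one or two compounds are
exchangeable), three single-product reactions per organism, a quarter of
reactions with two substrates, optionally one reference reaction, at most
twelve arcs and two tentacular arcs in the finished instance, one source,
two or three targets sampled from the closure of the source when a
feasible instance is requested. Identical parameters and seed give a
byte-identical serialized instance; infeasible parameter regions raise
after a bounded number of derived-seed retries.

What these instances do **not** emulate: genome-scale size (thousands of
arcs, hundreds of tentacular hyperarcs), hub metabolites with large
degree, realistic pathway depth, and multi-product reactions. Passing the
oracle sweeps therefore certifies algorithmic correctness at small scale,
not performance or biological realism at genome scale; the guardrails
exist precisely because the exact algorithm's parameters blow up on real
GEMs.

### Case-study fixtures

The three packaged instances reproduce the *composition and weight
accounting* of two published co-culture designs at desk scale, not the
KEGG networks behind them: chains of uninteresting intermediates are kept
at the published lengths so arc counts, and hence optimal weights, match
exactly (antibiotics: 28 endogenous + 3 insertions incl. the 3-substrate
tripeptide synthase + 2 transports = 528; PDO/methane: 10 endogenous + 1
transition = 110; with the acetate transport discounted to 50: 11
endogenous + 50 = 61). Each toy is built so its optimum is unique (single
chains, no alternative routes), which makes the regression checks sharp;
the genome-scale originals have several co-optimal route variants instead.
The serialized fixtures ship as package data and are regression-locked
against the construction code. The two PDO fixtures are small enough that
the brute-force oracle independently confirms their optima.

## Multi-product weight accounting

When several sibling arcs of one decomposed multi-product reaction appear
in one solution, the total weight counts each arc (the quantity the DP
optimizes — a conservative upper bound on "pay once per reaction"), while
the per-category breakdown counts distinct reactions. The exact convention
only matters for multi-product reactions; fixtures and the generator emit
single-product reactions, where the two coincide. Both views are exposed
(`total_weight` vs `breakdown`), and the default is documented here rather
than guessed silently.

## Known limitations

* Exponential in tentacular count and `|T′|` by design; genome-scale
  inputs need aggressive cofactor removal and compression, and may still
  exceed the guardrails (an ILP/ASP backend would be the practical
  alternative at that scale and is out of scope here).
* No stoichiometry means self-regenerating cycles are not excluded by
  balance arguments; rootedness alone guarantees every intermediate is
  produced at least once before use.
* Transition arcs are generated eagerly for every shared compound, which
  can dominate the arc count of dense multi-organism instances before
  compression.
* The enumeration cap bounds work but not peak memory of the memoized
  Steiner tables, which grow as `O(|V|·2^|T′|)`.
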