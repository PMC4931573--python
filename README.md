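# multipus

Exact design of microbial consortia: given the metabolic networks of a set
of candidate "worker" organisms, a set of available substrates and a set of
target compounds, `multipus` proposes the cheapest consortium design — which
organisms to use, which heterologous reactions to insert into them, and
which metabolites they must exchange — by solving the **Directed Steiner
Hypertree (DSH)** problem exactly on a weighted directed hypergraph.

It is written for computational/systems biologists exploring synthetic
co-cultures (e.g. pairing a producer bacterium with a methanogenic archaeon,
or splitting a heterologous pathway across species) who want provably
minimum-cost reaction sets rather than heuristic suggestions. The model is
purely topological: stoichiometry, flux and growth are out of scope (a flux
model is the natural post-processing step).

## Model

Each organism's network contributes vertices `(compound, organism)` and one
hyperarc per reaction: substrates `src(a)` → a single product `tgt(a)`
(multi-product reactions are decomposed; reversible ones are split). The
consortium hypergraph `H(V, A)` is the disjoint union of the worker
networks, plus:

* **insertion arcs** — a copy of every reference-organism reaction absent
  from a worker, placed in that worker at weight `w_other` (heterologous
  expression is costly; default 100);
* **transition arcs** — for every compound present in two organisms, an arc
  each way at weight `w_transition` (transport is costly; default 100,
  per-compound overrides supported);
* endogenous arcs keep weight `w_worker` (default 1, so among equally cheap
  designs the one using fewest internal reactions wins).

A hyperarc set `A'` is *rooted* at the sources `S` if its arcs can be
ordered so that every arc's substrates are supplied by `S` or by earlier
arcs' products. The DSH problem asks for a minimum-weight rooted `A'` with
`T ⊆ tgt(A')`.

A hyperarc with more than one substrate is *tentacular* (its *spreadness* is
its substrate count). The solver is exact and fixed-parameter tractable in
`|T|` + total spreadness:

1. enumerate every ordered subset `M = (a_1 … a_k)` of tentacular arcs
   (`2^k·k!` combinations — the order is the topological firing order);
2. for each `M`, the substrates of `M` join the targets
   (`T' = T ∪ src(M)`) and its products join the sources
   (`S' = S ∪ tgt(M)`), stratified into layers so a tree may only feed a
   target from a source produced strictly earlier; the cheapest forest
   covering `T'` solves the subset recursion

   ```
   SH_M(Y) = min(  min_{s ∈ S_Y} ST(s, Y),
                   min_{∅⊂Y'⊂Y} SH_M(Y') + SH_M(Y \ Y')  )
   ```

   with `S_Y = {s ∈ S' : Layer_S(s) < Layer_T(Y)}` and `ST(s, Y)` the
   directed Steiner tree on the graph left after deleting tentacular arcs
   (computed by the Dreyfus–Wagner subset dynamic program);
3. the optimum is `min_M weight(M) + SH_M(T')`; witnesses are rebuilt,
   pruned to inclusion-minimality and validated. An enumeration mode
   backtracks through every co-optimal choice and returns *all* distinct
   optimal designs.

Weights are exact rationals throughout; infeasibility is a reported
outcome, never a numeric sentinel leaking into results.

## Worked example

The packaged `pdo_acetate_toy` instance pairs a glycerol-fermenting
*Klebsiella pneumoniae* with the methanogen *Methanosarcina mazei* to make
1,3-propanediol and methane from glycerol, with the acetate transport
discounted to 50 (both species are known to move organic acids):

```python
from multipus import case_study_fixture, enumerate_optimal

inst = case_study_fixture("pdo_acetate_toy")
out = enumerate_optimal(inst, cap=10)
print("optimal weight:", out.optimal_weight)
for sol in out.solutions:
    print("breakdown:", dict(sorted(sol.breakdown.items())))
    print("firing order:", " -> ".join(sol.ordering))
```

prints

```
optimal weight: 61
breakdown: {'endogenous': 11, 'insertion': 0, 'transition': 1}
firing order: R_dhaB>3HPA@Kpneumoniae -> R_dhaT>PDO@Kpneumoniae -> R_glpK>glycerol3P@Kpneumoniae -> R_glpD>DHAP@Kpneumoniae -> R_tpi>G3P@Kpneumoniae -> R_gpm>PEP@Kpneumoniae -> R_pyk>pyruvate@Kpneumoniae -> R_poxB>acetate@Kpneumoniae -> tr:acetate:Kpneumoniae>Mmazei -> R_acs>acetylCoA@Mmazei -> R_cdh>methylCoM@Mmazei -> R_mcr>methane@Mmazei
```

i.e. the cheapest consortium (weight 61 = 11 endogenous reactions at 1 plus
the acetate transport at 50) ferments glycerol to PDO and to acetate in
*K. pneumoniae*, exchanges acetate, and lets *M. mazei* turn it into
methane — the archaeon simultaneously detoxifying the bacterium's
growth-inhibiting by-product. Without the acetate discount the optimum is
the 110-weight pyruvate-exchanging design (`pdo_toy`).

The same works from the shell, including DOT diagrams with one cluster per
organism:

```sh
multipus fixture pdo_toy --out pdo.json
multipus solve --seed-instance pdo.json --format dot --out pdo.dot
```

Networks are supplied as TSV tables (`reaction_id`, semicolon-separated
`substrates` and `products`, `reversible` 0/1) or SBML:

```sh
multipus solve --network KP=kpneumoniae.tsv --network MM=mmazei.tsv \
    --sources glycerol@KP --targets PDO@KP,methane@MM \
    --w-worker 1 --w-transition 100 --override transition:acetate=50 \
    --enumerate-all --out designs.json
```

Exit codes: 0 solved, 3 infeasible, 4 guardrail refusal, 1 usage/IO error.

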