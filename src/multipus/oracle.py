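"""Brute-force reference solver and seeded random-instance generator.

The brute-force solver enumerates *every* arc subset, keeps those that are
rooted at the sources (checked with the greedy scheduler, a code path the
dynamic-programming solver does not share) and produce every target, and
returns the minimum weight together with all inclusion-minimal optimal
subsets.  It is exponential and capped, but on small instances it is an
independent ground truth for both the optimal weight and the complete
optimal-solution set.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .builder import ConsortiumInstance, WeightConfig, build_instance
from .errors import GuardrailError, ValidationError
from .hypergraph import Reaction, SolutionHypertree, closure
from .solver import DshOutcome

ORACLE_ARC_LIMIT = 14


def brute_force_dsh(
    instance: ConsortiumInstance,
    allow_source_targets: bool = False,
    arc_limit: int = ORACLE_ARC_LIMIT,
) -> DshOutcome:
    """Exhaustive reference solution of the DSH problem.

    Subsets are scanned in order of increasing weight, so the scan stops as
    soon as the weight exceeds the best feasible one found; all optimal
    feasible subsets are then filtered to the inclusion-minimal ones.
    """
    instance.validate()
    h = instance.hypergraph
    arc_ids = sorted(h.hyperarcs)
    m = len(arc_ids)
    if m > arc_limit:
        raise GuardrailError(
            f"{m} arcs exceeds the oracle limit of {arc_limit} "
            f"(2^{m} subsets); raise arc_limit explicitly to override"
        )

    required = frozenset(
        instance.T - instance.S if allow_source_targets else instance.T
    )
    vidx = {v: i for i, v in enumerate(sorted(h.vertices))}
    src_mask = []
    tgt_bit = []
    weight = []
    for aid in arc_ids:
        a = h.hyperarcs[aid]
        sm = 0
        for s in a.sources:
            sm |= 1 << vidx[s]
        src_mask.append(sm)
        tgt_bit.append(1 << vidx[a.target])
        weight.append(a.weight)
    s_mask = 0
    for s in instance.S:
        s_mask |= 1 << vidx[s]
    req_mask = 0
    for t in required:
        req_mask |= 1 << vidx[t]

    # subset weights and produced-vertex masks by lowest-bit recurrence
    n_sub = 1 << m
    sub_w: list[Fraction] = [Fraction(0)] * n_sub
    sub_tgts = [0] * n_sub
    for sub in range(1, n_sub):
        low = sub & -sub
        i = low.bit_length() - 1
        sub_w[sub] = sub_w[sub ^ low] + weight[i]
        sub_tgts[sub] = sub_tgts[sub ^ low] | tgt_bit[i]

    def rooted(sub: int) -> bool:
        avail = s_mask
        pending = [i for i in range(m) if sub >> i & 1]
        progress = True
        while pending and progress:
            progress = False
            still = []
            for i in pending:
                if src_mask[i] & ~avail == 0:
                    avail |= tgt_bit[i]
                    progress = True
                else:
                    still.append(i)
            pending = still
        return not pending

    order = sorted(range(n_sub), key=lambda s: (sub_w[s], s))
    best: Optional[Fraction] = None
    optimal: list[int] = []
    for sub in order:
        if best is not None and sub_w[sub] > best:
            break
        if req_mask & ~sub_tgts[sub]:
            continue
        if not rooted(sub):
            continue
        best = sub_w[sub]
        optimal.append(sub)
    if best is None:
        return DshOutcome("infeasible", None, [], [])

    minimal = [
        sub
        for sub in optimal
        if not any(o != sub and o & ~sub == 0 for o in optimal)
    ]
    solutions = []
    for sub in minimal:
        ids = [arc_ids[i] for i in range(m) if sub >> i & 1]
        solutions.append(SolutionHypertree.from_arcs(h, ids, instance.S))
    solutions.sort(key=lambda s: s.key())
    return DshOutcome("optimal", best, solutions, [() for _ in solutions])


# ---------------------------------------------------------------------------
# Random instances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the seeded random-instance generator.

    Defaults describe the oracle-scale regime: two organisms drawing four
    compounds each from a slightly larger shared pool (so a couple of
    compounds are exchangeable), three reactions per organism, one in four
    reactions tentacular with at most two substrates, and occasionally one
    reference reaction to exercise insertion copies.  ``max_total_arcs``
    keeps the finished instance (including transitions) within brute-force
    reach; sampling retries with derived seeds until it fits.
    """

    n_organisms: int = 2
    n_compounds_per_organism: int = 4
    n_compound_pool: int = 7
    n_reactions_per_organism: int = 3
    tentacular_fraction: float = 0.25
    max_spreadness: int = 2
    n_reference_reactions: int = 0
    n_sources: int = 1
    n_targets: int = 2
    seed: int = 0
    weights: WeightConfig = field(default_factory=WeightConfig)
    feasible: bool = True
    max_total_arcs: int = 12
    max_tentacular_arcs: Optional[int] = 2
    max_attempts: int = 200

    def __post_init__(self) -> None:
        if not (0 <= self.tentacular_fraction <= 1):
            raise ValidationError("tentacular_fraction must be in [0, 1]")
        for name in (
            "n_organisms",
            "n_compounds_per_organism",
            "n_reactions_per_organism",
            "n_reference_reactions",
            "n_sources",
            "n_targets",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.n_organisms < 1 or self.n_targets < 1 or self.n_sources < 1:
            raise ValidationError("need at least one organism, source, target")
        if self.max_spreadness < 1:
            raise ValidationError("max_spreadness must be >= 1")
        if self.n_compound_pool < self.n_compounds_per_organism:
            raise ValidationError("compound pool smaller than per-organism need")


def _random_reactions(
    rng: random.Random,
    prefix: str,
    compounds: list[str],
    n_reactions: int,
    tentacular_fraction: float,
    max_spreadness: int,
) -> list[Reaction]:
    out = []
    for i in range(n_reactions):
        if max_spreadness > 1 and rng.random() < tentacular_fraction:
            n_src = rng.randint(2, max_spreadness)
        else:
            n_src = 1
        n_src = min(n_src, len(compounds) - 1)
        subs = rng.sample(compounds, n_src)
        prod = rng.choice([c for c in compounds if c not in subs])
        out.append(Reaction(f"{prefix}{i}", tuple(subs), (prod,)))
    return out


def generate_random_instance(params: GeneratorParams) -> ConsortiumInstance:
    """Deterministic random instance: identical params (including seed)
    always produce the identical instance."""
    last_err = "no attempt made"
    for attempt in range(params.max_attempts):
        rng = random.Random((params.seed * 1_000_003 + attempt) & 0x7FFFFFFF)
        pool = [f"c{i:02d}" for i in range(params.n_compound_pool)]
        orgs = [f"org{i + 1}" for i in range(params.n_organisms)]
        networks = []
        for oi, org in enumerate(orgs):
            compounds = sorted(
                rng.sample(pool, params.n_compounds_per_organism)
            )
            networks.append(
                (
                    org,
                    _random_reactions(
                        rng,
                        f"{org}_r",
                        compounds,
                        params.n_reactions_per_organism,
                        params.tentacular_fraction,
                        params.max_spreadness,
                    ),
                )
            )
        refs = _random_reactions(
            rng,
            "ref_r",
            pool,
            params.n_reference_reactions,
            params.tentacular_fraction,
            params.max_spreadness,
        )
        try:
            inst = build_instance(
                networks,
                sources=(),
                targets=(),
                reference_reactions=refs,
                weights=params.weights,
            )
        except ValidationError as exc:  # pragma: no cover - defensive
            last_err = str(exc)
            continue
        inst.validate(require_targets=False)
        h = inst.hypergraph
        if len(h.hyperarcs) > params.max_total_arcs:
            last_err = f"{len(h.hyperarcs)} arcs > {params.max_total_arcs}"
            continue
        if (
            params.max_tentacular_arcs is not None
            and len(h.tentacular_ids()) > params.max_tentacular_arcs
        ):
            last_err = "too many tentacular hyperarcs"
            continue
        vertices = sorted(h.vertices)
        if len(vertices) < params.n_sources:
            last_err = "too few vertices"
            continue
        S = frozenset(rng.sample(vertices, params.n_sources))
        if params.feasible:
            reachable = closure(h, h.hyperarcs.keys(), S)
            candidates = sorted(reachable - S)
            if len(candidates) < params.n_targets:
                last_err = "closure too small for requested targets"
                continue
            T = frozenset(rng.sample(candidates, params.n_targets))
        else:
            rest = sorted(set(vertices) - S)
            if len(rest) < params.n_targets:
                last_err = "too few vertices for targets"
                continue
            T = frozenset(rng.sample(rest, params.n_targets))
        return inst.with_terminals(S, T)
    raise ValidationError(
        f"could not generate an instance for {params} "
        f"after {params.max_attempts} attempts (last: {last_err})"
    )
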