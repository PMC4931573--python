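"""Named toy instances reproducing the two published consortium case
studies at desk scale.

These fixtures reproduce the *composition and weight accounting* of the
reported optimal consortium designs — how many endogenous reactions,
insertions and transports the cheapest design uses — not the genome-scale
KEGG networks behind them (which would require external extraction).  Chains
of uninteresting intermediate steps are kept at the published lengths so the
arc counts, and therefore the optimal weights, match exactly.

``antibiotics_toy``
    A *Streptomyces cattleya* / *Methanosarcina barkeri* pair producing
    penicillin and cephalosporin C from cellulose, with the tripeptide
    synthase (three substrates: L-2-aminoadipate, L-valine, L-cysteine — a
    tentacular reaction) and the two downstream beta-lactam steps available
    only from reference organisms.  The unique cheapest design uses
    2 transports, 3 insertions and 28 endogenous reactions: 528 under
    w_worker=1, w_other=100, w_transition=100.

``pdo_toy``
    A *Klebsiella pneumoniae* / *Methanosarcina mazei* pair turning glycerol
    into 1,3-propanediol and methane: 1 transition + 10 endogenous
    reactions = 110 under the same uniform weights.

``pdo_acetate_toy``
    Same pair with the acetate detour added; with the acetate transport
    discounted to 50 (organic-acid exchange is biologically cheap for this
    pair) the optimum becomes the acetate-exchanging design:
    1 transition at 50 + 11 endogenous reactions = 61.

The serialized forms of the three instances ship as package data and are
regression-locked against this construction code.
"""

from __future__ import annotations

from .builder import ConsortiumInstance, WeightConfig, build_instance
from .errors import ValidationError
from .hypergraph import Reaction, TRANSITION

FIXTURE_NAMES = ("antibiotics_toy", "pdo_toy", "pdo_acetate_toy")


def _chain(prefix: str, compounds: list[str]) -> list[Reaction]:
    """A linear chain of single-substrate reactions through ``compounds``."""
    return [
        Reaction(f"{prefix}{i + 1}", (a,), (b,))
        for i, (a, b) in enumerate(zip(compounds, compounds[1:]))
    ]


def _pdo_networks(with_acetate: bool):
    kp = [
        # glycerol -> 1,3-propanediol (dehydratase then oxidoreductase)
        Reaction("R_dhaB", ("glycerol",), ("3HPA",)),
        Reaction("R_dhaT", ("3HPA",), ("PDO",)),
        # glycerol -> pyruvate (glycolytic route, five steps)
        Reaction("R_glpK", ("glycerol",), ("glycerol3P",)),
        Reaction("R_glpD", ("glycerol3P",), ("DHAP",)),
        Reaction("R_tpi", ("DHAP",), ("G3P",)),
        Reaction("R_gpm", ("G3P",), ("PEP",)),
        Reaction("R_pyk", ("PEP",), ("pyruvate",)),
    ]
    mm = [
        # methanogenesis from pyruvate
        Reaction("R_por", ("pyruvate",), ("acetylCoA",)),
        Reaction("R_cdh", ("acetylCoA",), ("methylCoM",)),
        Reaction("R_mcr", ("methylCoM",), ("methane",)),
    ]
    if with_acetate:
        # the acetate detour: made in K. pneumoniae, consumed by M. mazei
        kp.append(Reaction("R_poxB", ("pyruvate",), ("acetate",)))
        mm.append(Reaction("R_acs", ("acetate",), ("acetylCoA",)))
    return [("Kpneumoniae", kp), ("Mmazei", mm)]


def _antibiotics_networks():
    sc = [
        # cellulose -> pyruvate (eight steps)
        *_chain(
            "R_gly",
            [
                "cellulose",
                "glucose",
                "G6P",
                "F6P",
                "FBP",
                "G3P",
                "PG3",
                "PEP",
                "pyruvate",
            ],
        ),
        # pyruvate -> L-valine (five steps)
        *_chain(
            "R_val",
            ["pyruvate", "acetolactate", "DHIV", "KIV", "preVal", "valine"],
        ),
        # pyruvate -> L-cysteine (five steps)
        *_chain(
            "R_cys",
            ["pyruvate", "cysInt1", "cysInt2", "cysInt3", "cysInt4", "cysteine"],
        ),
        # aminoadipate aminotransferase: only S. cattleya has it
        Reaction("R_aadat", ("2oxoadipate",), ("L2aminoadipate",)),
        # isopenicillin N -> penicillin (three steps)
        *_chain("R_pen", ["isopenicillinN", "6APA", "penInt", "penicillin"]),
    ]
    mb = [
        # pyruvate -> 2-oxoadipate: the oxoadipate branch lives in the
        # archaeon only, which is what forces the two transports
        *_chain(
            "R_mb",
            ["pyruvate", "mbInt1", "mbInt2", "mbInt3", "mbInt4", "mbInt5", "2oxoadipate"],
        ),
    ]
    references = [
        # tripeptide synthase: the three-substrate (tentacular) step
        Reaction(
            "R_acvs",
            ("L2aminoadipate", "valine", "cysteine"),
            ("ACV",),
        ),
        Reaction("R_ipns", ("ACV",), ("isopenicillinN",)),
        Reaction("R_cefX", ("isopenicillinN",), ("cephalosporinC",)),
    ]
    return [("Scattleya", sc), ("Mbarkeri", mb)], references


def case_study_fixture(name: str) -> ConsortiumInstance:
    """Build one of the packaged case-study instances by name."""
    if name == "antibiotics_toy":
        networks, references = _antibiotics_networks()
        return build_instance(
            networks,
            sources=["cellulose@Scattleya"],
            targets=["penicillin@Scattleya", "cephalosporinC@Scattleya"],
            reference_reactions=references,
            weights=WeightConfig(w_worker=1, w_other=100, w_transition=100),
        )
    if name == "pdo_toy":
        return build_instance(
            _pdo_networks(with_acetate=False),
            sources=["glycerol@Kpneumoniae"],
            targets=["PDO@Kpneumoniae", "methane@Mmazei"],
            weights=WeightConfig(w_worker=1, w_other=100, w_transition=100),
        )
    if name == "pdo_acetate_toy":
        return build_instance(
            _pdo_networks(with_acetate=True),
            sources=["glycerol@Kpneumoniae"],
            targets=["PDO@Kpneumoniae", "methane@Mmazei"],
            weights=WeightConfig(
                w_worker=1,
                w_other=100,
                w_transition=100,
                overrides={(TRANSITION, "acetate"): 50},
            ),
        )
    raise ValidationError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
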