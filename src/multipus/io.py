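"""File formats: instance documents (JSON), network tables (TSV), SBML
input, cofactor lists, and solution export (JSON / DOT).

Serialization is deterministic — identical inputs give byte-identical
output — and every reader rejects malformed input with the file and
location named, rather than silently coercing.
"""

from __future__ import annotations

import csv
import json
from collections.abc import Sequence
from fractions import Fraction
from pathlib import Path
from typing import Union

from .builder import ConsortiumInstance, WeightConfig
from .errors import ValidationError
from .hypergraph import (
    CATEGORIES,
    Hyperarc,
    Hypergraph,
    Reaction,
    Vertex,
)
from .solver import DshOutcome

SCHEMA_VERSION = 1

#: shape of an instance document, published for external validators
INSTANCE_SCHEMA = {
    "type": "object",
    "required": ["schema_version", "vertices", "arcs", "sources", "targets", "weights"],
    "properties": {
        "schema_version": {"const": SCHEMA_VERSION},
        "vertices": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["id", "compound", "organism"],
            },
        },
        "arcs": {
            "type": "array",
            "items": {
                "type": "object",
                "required": [
                    "id",
                    "reaction",
                    "sources",
                    "target",
                    "weight",
                    "category",
                    "organism",
                ],
            },
        },
        "sources": {"type": "array", "items": {"type": "string"}},
        "targets": {"type": "array", "items": {"type": "string"}},
        "weights": {
            "type": "object",
            "required": ["w_worker", "w_other", "w_transition", "overrides"],
        },
        "worker_organisms": {"type": "array", "items": {"type": "string"}},
        "reference_reactions": {"type": "array", "items": {"type": "string"}},
    },
}


def _weight_str(w: Fraction) -> Union[int, str]:
    return int(w) if w.denominator == 1 else str(w)


def _parse_weight(raw, where: str) -> Fraction:
    try:
        return Fraction(raw)
    except (ValueError, TypeError, ZeroDivisionError) as exc:
        raise ValidationError(f"{where}: bad weight {raw!r}") from exc


# ---------------------------------------------------------------------------
# Instance documents
# ---------------------------------------------------------------------------


def instance_to_document(instance: ConsortiumInstance) -> dict:
    h = instance.hypergraph
    w = instance.weights
    return {
        "schema_version": SCHEMA_VERSION,
        "vertices": [
            {
                "id": v.id,
                "compound": v.compound_id,
                "organism": v.organism,
            }
            for v in sorted(h.vertices.values(), key=lambda v: v.id)
        ],
        "arcs": [
            {
                "id": a.id,
                "reaction": a.reaction_id,
                "sources": sorted(a.sources),
                "target": a.target,
                "weight": _weight_str(a.weight),
                "category": a.category,
                "organism": list(a.organism)
                if isinstance(a.organism, tuple)
                else a.organism,
            }
            for a in sorted(h.hyperarcs.values(), key=lambda a: a.id)
        ],
        "sources": sorted(instance.S),
        "targets": sorted(instance.T),
        "weights": {
            "w_worker": _weight_str(w.w_worker),
            "w_other": _weight_str(w.w_other),
            "w_transition": _weight_str(w.w_transition),
            "overrides": [
                {"category": cat, "key": key, "weight": _weight_str(val)}
                for (cat, key), val in sorted(w.overrides.items())
            ],
        },
        "worker_organisms": list(instance.worker_organisms),
        "reference_reactions": list(instance.reference_reaction_ids),
    }


def _require(doc: dict, key: str, typ, where: str):
    if key not in doc:
        raise ValidationError(f"{where}: missing required field {key!r}")
    val = doc[key]
    if not isinstance(val, typ):
        raise ValidationError(
            f"{where}: field {key!r} must be {typ.__name__}, got {type(val).__name__}"
        )
    return val


def instance_from_document(doc: dict, where: str = "<document>") -> ConsortiumInstance:
    if _require(doc, "schema_version", int, where) != SCHEMA_VERSION:
        raise ValidationError(
            f"{where}: unsupported schema_version {doc['schema_version']!r}"
        )
    h = Hypergraph()
    for i, v in enumerate(_require(doc, "vertices", list, where)):
        loc = f"{where}: vertices[{i}]"
        h.add_vertex(
            Vertex(
                _require(v, "id", str, loc),
                _require(v, "compound", str, loc),
                _require(v, "organism", str, loc),
            )
        )
    for i, a in enumerate(_require(doc, "arcs", list, where)):
        loc = f"{where}: arcs[{i}]"
        org = a.get("organism")
        if isinstance(org, list):
            if len(org) != 2:
                raise ValidationError(f"{loc}: transition organism must be a pair")
            org = (org[0], org[1])
        elif not isinstance(org, str):
            raise ValidationError(f"{loc}: bad organism field")
        h.add_arc(
            Hyperarc(
                _require(a, "id", str, loc),
                _require(a, "reaction", str, loc),
                frozenset(_require(a, "sources", list, loc)),
                _require(a, "target", str, loc),
                _parse_weight(a.get("weight"), loc),
                _require(a, "category", str, loc),
                org,
            )
        )
    wdoc = _require(doc, "weights", dict, where)
    overrides = {}
    for i, o in enumerate(wdoc.get("overrides", [])):
        loc = f"{where}: weights.overrides[{i}]"
        cat = _require(o, "category", str, loc)
        if cat not in CATEGORIES:
            raise ValidationError(f"{loc}: unknown category {cat!r}")
        overrides[(cat, _require(o, "key", str, loc))] = _parse_weight(
            o.get("weight"), loc
        )
    weights = WeightConfig(
        w_worker=_parse_weight(wdoc.get("w_worker"), where),
        w_other=_parse_weight(wdoc.get("w_other"), where),
        w_transition=_parse_weight(wdoc.get("w_transition"), where),
        overrides=overrides,
    )
    inst = ConsortiumInstance(
        hypergraph=h,
        weights=weights,
        worker_organisms=tuple(doc.get("worker_organisms", [])),
        reference_reaction_ids=tuple(doc.get("reference_reactions", [])),
    )
    inst = inst.with_terminals(
        _require(doc, "sources", list, where),
        _require(doc, "targets", list, where),
    )
    inst.validate(require_targets=False)
    return inst


def dumps_instance(instance: ConsortiumInstance) -> str:
    return json.dumps(instance_to_document(instance), indent=1, sort_keys=True) + "\n"


def write_instance(instance: ConsortiumInstance, path) -> None:
    Path(path).write_text(dumps_instance(instance), encoding="utf-8")


def read_instance(path) -> ConsortiumInstance:
    p = Path(path)
    try:
        doc = json.loads(p.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{p}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise ValidationError(f"{p}: instance document must be a JSON object")
    return instance_from_document(doc, where=str(p))


# ---------------------------------------------------------------------------
# Network tables (TSV)
# ---------------------------------------------------------------------------

NETWORK_HEADER = ["reaction_id", "substrates", "products", "reversible"]


def read_network_table(path) -> list[Reaction]:
    """Read a per-organism reaction table.

    Tab-separated, UTF-8, header row ``reaction_id  substrates  products
    reversible``; compound lists are semicolon-separated; reversible is 0/1.
    """
    p = Path(path)
    out: list[Reaction] = []
    seen: set[str] = set()
    with p.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{p}: empty file, header row required")
        if [c.strip() for c in header] != NETWORK_HEADER:
            raise ValidationError(
                f"{p}:1: bad header {header!r}, expected {NETWORK_HEADER!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise ValidationError(
                    f"{p}:{lineno}: expected 4 tab-separated fields, got {len(row)}"
                )
            rid, subs, prods, rev = (c.strip() for c in row)
            if not rid:
                raise ValidationError(f"{p}:{lineno}: empty reaction_id")
            if rid in seen:
                raise ValidationError(f"{p}:{lineno}: duplicate reaction_id {rid!r}")
            seen.add(rid)
            substrates = tuple(s for s in subs.split(";") if s)
            products = tuple(s for s in prods.split(";") if s)
            if not substrates or not products:
                raise ValidationError(
                    f"{p}:{lineno}: reaction {rid!r} needs at least one "
                    f"substrate and one product"
                )
            if rev not in ("0", "1"):
                raise ValidationError(
                    f"{p}:{lineno}: reversible must be 0 or 1, got {rev!r}"
                )
            out.append(Reaction(rid, substrates, products, rev == "1"))
    return out


def write_network_table(reactions: Sequence[Reaction], path) -> None:
    lines = ["\t".join(NETWORK_HEADER)]
    for r in reactions:
        lines.append(
            "\t".join(
                [
                    r.reaction_id,
                    ";".join(r.substrates),
                    ";".join(r.products),
                    "1" if r.reversible else "0",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_cofactor_list(path) -> set[str]:
    """One compound id per line; blank lines and ``#`` comments ignored."""
    out = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        item = line.split("#", 1)[0].strip()
        if item:
            out.add(item)
    return out


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------


def read_sbml(path, strip_compartment_suffix: bool = False) -> list[Reaction]:
    """Read species/reaction topology from an SBML Level 2/3 core document.

    Stoichiometric coefficients are ignored (the model is topological) and
    reversibility is honoured.  Reactions with no reactants or no products
    are skipped.  With ``strip_compartment_suffix``, a trailing
    ``_<compartmentId>`` is removed from species ids, so ``glc_c`` and
    ``glc_e`` merge when ``c`` and ``e`` are declared compartments.
    """
    try:
        import libsbml
    except ImportError as exc:  # pragma: no cover
        raise ValidationError(
            "SBML support requires the python-libsbml package"
        ) from exc
    p = Path(path)
    doc = libsbml.readSBMLFromString(p.read_text(encoding="utf-8"))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValidationError(f"{p}: SBML parse error: {first.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise ValidationError(f"{p}: SBML document contains no model")
    compartments = {
        model.getCompartment(i).getId()
        for i in range(model.getNumCompartments())
    }

    def species_name(sid: str) -> str:
        if strip_compartment_suffix:
            for comp in compartments:
                if comp and sid.endswith(f"_{comp}"):
                    return sid[: -(len(comp) + 1)]
        return sid

    out: list[Reaction] = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        subs = tuple(
            species_name(rxn.getReactant(j).getSpecies())
            for j in range(rxn.getNumReactants())
        )
        prods = tuple(
            species_name(rxn.getProduct(j).getSpecies())
            for j in range(rxn.getNumProducts())
        )
        if not subs or not prods:
            continue
        out.append(Reaction(rxn.getId(), subs, prods, bool(rxn.getReversible())))
    return out


# ---------------------------------------------------------------------------
# Solution export
# ---------------------------------------------------------------------------


def outcome_to_document(
    outcome: DshOutcome, instance: ConsortiumInstance
) -> dict:
    h = instance.hypergraph
    doc: dict = {
        "status": outcome.status,
        "optimal_weight": None
        if outcome.optimal_weight is None
        else _weight_str(outcome.optimal_weight),
        "truncated": outcome.truncated,
        "solutions": [],
    }
    for sol, combo in zip(outcome.solutions, outcome.combinations_used):
        arcs = []
        for aid in sorted(sol.arcs):
            a = h.hyperarcs[aid]
            arcs.append(
                {
                    "id": aid,
                    "reaction": a.reaction_id,
                    "sources": sorted(a.sources),
                    "target": a.target,
                    "weight": _weight_str(a.weight),
                    "category": a.category,
                    "organism": list(a.organism)
                    if isinstance(a.organism, tuple)
                    else a.organism,
                }
            )
        doc["solutions"].append(
            {
                "arcs": arcs,
                "ordering": list(sol.ordering),
                "total_weight": _weight_str(sol.total_weight),
                "breakdown": dict(sorted(sol.breakdown.items())),
                "tentacular_combination": list(combo),
            }
        )
    return doc


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def outcome_to_dot(outcome: DshOutcome, instance: ConsortiumInstance) -> str:
    """Render the first solution as Graphviz DOT: one cluster per organism,
    arc style by category (solid endogenous, dashed insertion, bold
    transition), point-shaped junction nodes for tentacular reactions."""
    h = instance.hypergraph
    lines = ["digraph consortium {", "  rankdir=LR;"]
    if not outcome.solutions:
        lines.append('  label="infeasible instance";')
        lines.append("}")
        return "\n".join(lines) + "\n"
    sol = outcome.solutions[0]
    used_vertices: set[str] = set()
    for aid in sol.arcs:
        a = h.hyperarcs[aid]
        used_vertices |= a.sources | {a.target}
    by_org: dict[str, list[str]] = {}
    for vid in sorted(used_vertices):
        by_org.setdefault(h.vertices[vid].organism, []).append(vid)
    for i, org in enumerate(sorted(by_org)):
        lines.append(f"  subgraph cluster_{i} {{")
        lines.append(f'    label="{_dot_escape(org)}";')
        for vid in by_org[org]:
            v = h.vertices[vid]
            lines.append(
                f'    "{_dot_escape(vid)}" [label="{_dot_escape(v.compound_id)}"];'
            )
        lines.append("  }")
    styles = {
        "endogenous": "style=solid",
        "insertion": "style=dashed color=purple",
        "transition": "style=bold color=green",
    }
    for aid in sorted(sol.arcs):
        a = h.hyperarcs[aid]
        style = styles[a.category]
        if len(a.sources) > 1:
            junction = f"junction_{_dot_escape(aid)}"
            lines.append(f'  "{junction}" [shape=point label=""];')
            for s in sorted(a.sources):
                lines.append(
                    f'  "{_dot_escape(s)}" -> "{junction}" [{style} arrowhead=none];'
                )
            lines.append(f'  "{junction}" -> "{_dot_escape(a.target)}" [{style}];')
        else:
            (s,) = a.sources
            lines.append(
                f'  "{_dot_escape(s)}" -> "{_dot_escape(a.target)}" '
                f'[{style} label="{_dot_escape(a.reaction_id)}"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_solutions(
    outcome: DshOutcome,
    instance: ConsortiumInstance,
    path,
    format: str = "json",
) -> None:
    """Write solver output: ``json`` (full, machine-readable, all solutions)
    or ``dot`` (diagram of the first solution)."""
    p = Path(path)
    if format == "json":
        doc = outcome_to_document(outcome, instance)
        p.write_text(
            json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
    elif format == "dot":
        p.write_text(outcome_to_dot(outcome, instance), encoding="utf-8")
    else:
        raise ValidationError(f"unknown output format {format!r} (json|dot)")
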