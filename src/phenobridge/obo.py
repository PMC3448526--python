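"""Reading and writing the OBO 1.2 subset used by the pipeline.

Parsing is delegated to :mod:`obonet`; this module adds the contract checks
(stanza validation, cycle detection via :class:`~phenobridge.ontology.Ontology`)
and extracts the Entity-Quality definition dialect:

* the first ``intersection_of:`` line of a block names the quality (genus);
* each following ``intersection_of: inheres_in ENTITY_ID`` line names an
  entity the quality inheres in;
* a new bare quality line starts the next conjunct block.

Only ``id``, ``name``, ``synonym``, ``is_a``, ``is_obsolete`` and
``intersection_of`` are interpreted; other relationship types are counted
and reported through a logger, never traversed.
"""

from __future__ import annotations

import io
import logging
import re

import obonet

from .errors import ParseError, ValidationError
from .ontology import (
    Concept,
    ConceptID,
    EQConjunct,
    EQDefinition,
    Ontology,
    validate_eq_definition,
)

logger = logging.getLogger(__name__)

_SYNONYM_RE = re.compile(r'^\s*"(.*)"\s*([A-Z_]*)')


def _check_stanzas(text: str) -> set[str]:
    """Validate [Term] stanzas and return the set of declared term IDs.

    Raises :class:`ParseError` for a stanza without an id tag.  The declared
    set distinguishes real terms from nodes the graph parser materializes
    implicitly for dangling is_a targets.
    """
    declared: set[str] = set()
    stanza_ordinal = 0
    in_term = False
    has_id = False
    for line in text.splitlines() + ["[Term]"]:  # sentinel flushes the last
        stripped = line.strip()
        if stripped.startswith("["):
            if in_term and not has_id:
                raise ParseError(f"[Term] stanza #{stanza_ordinal} has no id tag")
            in_term = stripped == "[Term]"
            if in_term:
                stanza_ordinal += 1
                has_id = False
        elif in_term and stripped.startswith("id:"):
            has_id = True
            declared.add(stripped[3:].split("!")[0].strip())
    return declared


def _split_synonym(raw: str) -> tuple[str, str]:
    """Return (text, scope) from a raw ``synonym`` tag value."""
    m = _SYNONYM_RE.match(raw)
    if m is None:
        return raw.strip(), ""
    return m.group(1), m.group(2)


def parse_obo(
    text: str,
    prefix: str | None = None,
    name: str = "",
    exact_synonyms_only: bool = False,
) -> Ontology:
    """Parse an OBO document into an :class:`Ontology`.

    Parameters
    ----------
    text:
        Full OBO document.
    prefix:
        Expected ID prefix; inferred from the first term when omitted.
    exact_synonyms_only:
        Keep only EXACT-scoped synonyms.  By default every synonym enters
        the concept regardless of scope (scope annotations are dropped).
    """
    declared = _check_stanzas(text)
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    concepts: list[Concept] = []
    n_other_rel = 0
    for node, data in graph.nodes(data=True):
        if node not in declared:
            continue  # implicit node for a dangling is_a target
        synonyms = []
        for raw in data.get("synonym", []):
            syn_text, scope = _split_synonym(raw)
            if exact_synonyms_only and scope != "EXACT":
                continue
            synonyms.append(syn_text)
        n_other_rel += len(data.get("relationship", []))
        concepts.append(
            Concept(
                id=node,
                label=data.get("name", ""),
                synonyms=synonyms,
                parent_ids=list(dict.fromkeys(data.get("is_a", []))),
                obsolete=data.get("is_obsolete", "false") == "true",
            )
        )
    if n_other_rel:
        logger.warning(
            "ignored %d non-is_a relationship line(s); only is_a is traversed",
            n_other_rel,
        )
    if prefix is None:
        if not concepts:
            raise ParseError("cannot infer prefix from an empty document")
        prefix = concepts[0].id.split(":", 1)[0]
    try:
        return Ontology(prefix, concepts, name=name)
    except ValidationError:
        raise


def write_obo(ontology: Ontology) -> str:
    """Serialize an ontology back to the OBO subset.

    Round-trips with :func:`parse_obo` on (ids, labels, synonyms, edges);
    synonym scopes, which the parser drops, are emitted as EXACT.
    """
    lines = ["format-version: 1.2", f"ontology: {ontology.name or ontology.prefix}"]
    for cid in sorted(ontology.concepts):
        c = ontology.concepts[cid]
        lines += ["", "[Term]", f"id: {c.id}"]
        if c.label:
            lines.append(f"name: {c.label}")
        for syn in c.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        for p in sorted(c.parent_ids):
            lines.append(f"is_a: {p}")
        if c.obsolete:
            lines.append("is_obsolete: true")
    return "\n".join(lines) + "\n"


def parse_eq_definitions(
    text: str,
    qualities: Ontology | None = None,
    entities: Ontology | None = None,
) -> dict[ConceptID, EQDefinition]:
    """Extract EQ definitions from ``intersection_of`` tags.

    Terms without ``intersection_of`` tags are absent from the result.  When
    support ontologies are supplied, every referenced quality/entity ID must
    resolve in them or a :class:`ValidationError` naming the offenders is
    raised.
    """
    _check_stanzas(text)
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    out: dict[ConceptID, EQDefinition] = {}
    for node, data in graph.nodes(data=True):
        raw_lines = data.get("intersection_of", [])
        if not raw_lines:
            continue
        conjuncts: list[EQConjunct] = []
        quality: ConceptID | None = None
        entities_seen = 0
        for raw in raw_lines:
            tokens = raw.split()
            if tokens and tokens[0] == "inheres_in":
                if quality is None or len(tokens) < 2:
                    raise ParseError(
                        f"{node}: inheres_in differentia before any quality genus"
                    )
                conjuncts.append(EQConjunct(quality=quality, entity=tokens[1]))
                entities_seen += 1
            else:
                if quality is not None and entities_seen == 0:
                    raise ParseError(
                        f"{node}: quality genus {quality} has no inheres_in line"
                    )
                quality = tokens[0]
                entities_seen = 0
        if quality is not None and entities_seen == 0:
            raise ParseError(f"{node}: quality genus {quality} has no inheres_in line")
        definition = EQDefinition(concept=node, conjuncts=tuple(conjuncts))
        if qualities is not None and entities is not None:
            validate_eq_definition(definition, qualities, entities)
        out[node] = definition
    return out


def write_eq_definitions(definitions: dict[ConceptID, EQDefinition]) -> str:
    """Serialize EQ definitions as OBO stanzas with intersection_of tags."""
    lines = ["format-version: 1.2"]
    for cid in sorted(definitions):
        d = definitions[cid]
        lines += ["", "[Term]", f"id: {cid}"]
        for cj in d.conjuncts:
            lines.append(f"intersection_of: {cj.quality}")
            lines.append(f"intersection_of: inheres_in {cj.entity}")
    return "\n".join(lines) + "\n"
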