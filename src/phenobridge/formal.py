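"""Cross-ontology axioms from EQ definitions by structural subsumption.

Phenotype concepts defined as conjunctions of (quality, entity) pairs over
shared support ontologies admit a simple, complete subsumption test: a
definition ``d1`` is subsumed by ``d2`` when every conjunct of ``d2`` is
generalized by some conjunct of ``d1``, where one conjunct generalizes
another iff its quality and entity are each ancestors-or-self of the
other's in the support hierarchies.  This is the standard structural rule
for flat existential conjunctions and plays the role an EL reasoner plays
on the full ontologies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import ParseError
from .ontology import (
    ConceptID,
    EQConjunct,
    EQDefinition,
    Ontology,
    concept_prefix,
)

AXIOM_KINDS = ("subclass", "equivalent")


@dataclass(frozen=True, order=True)
class MappingAxiom:
    """A cross-ontology ``sub SubClassOf super`` or equivalence axiom.

    Equivalence axioms are stored once, oriented by the caller (by
    convention ontology-1 concept first).
    """

    kind: str
    sub: ConceptID
    super: ConceptID

    def __post_init__(self) -> None:
        if self.kind not in AXIOM_KINDS:
            raise ValueError(f"unknown axiom kind: {self.kind}")
        if concept_prefix(self.sub) == concept_prefix(self.super):
            raise ValueError(
                f"axiom within one ontology: {self.sub} {self.super}"
            )


def conjunct_subsumes(
    c1: EQConjunct, c2: EQConjunct, qualities: Ontology, entities: Ontology
) -> bool:
    """True iff conjunct ``c2`` generalizes (or equals) conjunct ``c1``."""
    return c2.quality in qualities.ancestors(
        c1.quality, include_self=True
    ) and c2.entity in entities.ancestors(c1.entity, include_self=True)


def eq_subsumes(
    d1: EQDefinition, d2: EQDefinition, qualities: Ontology, entities: Ontology
) -> bool:
    """True iff ``d2`` subsumes ``d1``: every conjunct of ``d2`` is covered.

    Each conjunct of the more general definition must be generalized by at
    least one conjunct of the more specific one.
    """
    return all(
        any(conjunct_subsumes(x, y, qualities, entities) for x in d1.conjuncts)
        for y in d2.conjuncts
    )


def formal_axioms(
    defs1: Mapping[ConceptID, EQDefinition],
    defs2: Mapping[ConceptID, EQDefinition],
    qualities: Ontology,
    entities: Ontology,
) -> set[MappingAxiom]:
    """All subclass/equivalence axioms between two EQ-defined concept sets.

    For every pair (a, b) across the two definition maps, emits
    ``a subclass b`` when b subsumes a, ``b subclass a`` for the converse,
    and a single ``equivalent`` axiom (oriented a-first) when both hold.
    """
    axioms: set[MappingAxiom] = set()
    for a, da in defs1.items():
        for b, db in defs2.items():
            forward = eq_subsumes(da, db, qualities, entities)
            backward = eq_subsumes(db, da, qualities, entities)
            if forward and backward:
                axioms.add(MappingAxiom(kind="equivalent", sub=a, super=b))
            elif forward:
                axioms.add(MappingAxiom(kind="subclass", sub=a, super=b))
            elif backward:
                axioms.add(MappingAxiom(kind="subclass", sub=b, super=a))
    return axioms


def write_axioms(axioms: Iterable[MappingAxiom]) -> str:
    """TSV serialization: ``sub_id<TAB>kind<TAB>super_id``."""
    return "".join(f"{a.sub}\t{a.kind}\t{a.super}\n" for a in sorted(axioms))


def parse_axioms(text: str) -> set[MappingAxiom]:
    """Read axioms from the three-column TSV form."""
    axioms: set[MappingAxiom] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        tokens = line.split("\t")
        if len(tokens) != 3:
            raise ParseError(f"line {lineno}: expected sub<TAB>kind<TAB>super")
        axioms.add(MappingAxiom(sub=tokens[0], kind=tokens[1], super=tokens[2]))
    return axioms
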