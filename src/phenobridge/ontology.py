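"""In-memory model of an OBO-style phenotype ontology.

An :class:`Ontology` is a directed acyclic graph of concepts connected by
``is_a`` edges, each concept carrying a primary label and optional synonyms.
Phenotype concepts may additionally be grounded by an Entity-Quality (EQ)
definition: a conjunction of (quality, entity) pairs whose members live in
two shared support ontologies (a PATO-like quality hierarchy and an
anatomy-like entity hierarchy).  Only ``is_a`` is traversed; subsumption
queries reduce to reflexive-transitive closure over that relation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import ConceptLookupError, ValidationError

#: Concept identifiers are strings of the form ``PREFIX:digits`` (or more
#: generally ``PREFIX:local``); comparison is case-sensitive string equality.
ConceptID = str

_ID_RE = re.compile(r"^([^\s:]+):(\S+)$")


def concept_prefix(concept_id: ConceptID) -> str:
    """Return the prefix of a ``PREFIX:local`` identifier.

    Raises :class:`ValueError` for identifiers without a non-empty prefix
    and local part.
    """
    m = _ID_RE.match(concept_id)
    if m is None:
        raise ValueError(f"malformed concept ID: {concept_id!r}")
    return m.group(1)


@dataclass
class Concept:
    """A single ontology class: label, synonyms, asserted parents."""

    id: ConceptID
    label: str = ""
    synonyms: list[str] = field(default_factory=list)
    parent_ids: list[ConceptID] = field(default_factory=list)
    obsolete: bool = False

    def __post_init__(self) -> None:
        concept_prefix(self.id)  # validate the identifier shape
        if len(set(self.parent_ids)) != len(self.parent_ids):
            raise ValidationError(f"{self.id}: duplicate parent IDs")


@dataclass(frozen=True)
class EQConjunct:
    """One (quality, entity) pair of an EQ definition."""

    quality: ConceptID
    entity: ConceptID


@dataclass(frozen=True)
class EQDefinition:
    """EQ grounding of a phenotype concept: a conjunction of conjuncts."""

    concept: ConceptID
    conjuncts: tuple[EQConjunct, ...]

    def __post_init__(self) -> None:
        if not self.conjuncts:
            raise ValidationError(f"{self.concept}: empty EQ definition")
        if len(set(self.conjuncts)) != len(self.conjuncts):
            raise ValidationError(f"{self.concept}: duplicate EQ conjuncts")


class Ontology:
    """A set of concepts under one ID prefix with an acyclic ``is_a`` graph.

    Parameters
    ----------
    prefix:
        ID prefix shared by every concept (e.g. ``"HP"``).
    concepts:
        The concepts, keyed or listed in any order.
    name:
        Human-readable ontology name.

    Obsolete concepts are retained for bookkeeping but are isolated in the
    traversal graph: their parents are ignored and they are excluded from
    matching and mapping pools.
    """

    def __init__(
        self,
        prefix: str,
        concepts: Iterable[Concept] | Mapping[ConceptID, Concept],
        name: str = "",
    ) -> None:
        if isinstance(concepts, Mapping):
            concepts = concepts.values()
        self.prefix = prefix
        self.name = name
        self.concepts: dict[ConceptID, Concept] = {c.id: c for c in concepts}
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(self.concepts)
        for c in self.concepts.values():
            if c.obsolete:
                continue
            for p in c.parent_ids:
                if concept_prefix(p) != self.prefix:
                    continue  # foreign-prefix parents are not traversed
                if p not in self.concepts:
                    raise ValidationError(
                        f"{c.id}: parent {p} does not resolve in ontology "
                        f"{self.prefix!r}"
                    )
                self._graph.add_edge(c.id, p)  # child -> parent
        try:
            cycle = nx.find_cycle(self._graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(u for u, _ in cycle) + f" -> {cycle[0][0]}"
            raise ValidationError(f"is_a cycle detected: {path}")
        self._ancestor_cache: dict[ConceptID, frozenset[ConceptID]] = {}

    # -- container protocol -------------------------------------------------
    def __contains__(self, concept_id: ConceptID) -> bool:
        return concept_id in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self) -> Iterator[ConceptID]:
        return iter(self.concepts)

    def __getitem__(self, concept_id: ConceptID) -> Concept:
        try:
            return self.concepts[concept_id]
        except KeyError:
            raise ConceptLookupError(concept_id) from None

    def active_ids(self) -> list[ConceptID]:
        """IDs of non-obsolete concepts, in insertion order."""
        return [cid for cid, c in self.concepts.items() if not c.obsolete]

    # -- traversal ----------------------------------------------------------
    def ancestors(
        self, concept_id: ConceptID, include_self: bool = False
    ) -> frozenset[ConceptID]:
        """Reflexive-transitive (or strict) ``is_a`` closure of a concept.

        Returns the strict closure when ``include_self`` is false, the
        reflexive closure otherwise.  Unknown IDs raise
        :class:`ConceptLookupError`.
        """
        if concept_id not in self.concepts:
            raise ConceptLookupError(concept_id)
        strict = self._ancestor_cache.get(concept_id)
        if strict is None:
            # memoized DFS; graph is guaranteed acyclic at construction
            strict = self._strict_ancestors(concept_id)
            self._ancestor_cache[concept_id] = strict
        if include_self:
            return strict | {concept_id}
        return strict

    def _strict_ancestors(self, concept_id: ConceptID) -> frozenset[ConceptID]:
        out: set[ConceptID] = set()
        for parent in self._graph.successors(concept_id):
            if parent in out:
                continue
            cached = self._ancestor_cache.get(parent)
            if cached is None:
                cached = self._strict_ancestors(parent)
                self._ancestor_cache[parent] = cached
            out.add(parent)
            out |= cached
        return frozenset(out)

    def graph(self) -> nx.DiGraph:
        """Copy of the child->parent ``is_a`` graph over active concepts."""
        return self._graph.copy()


def ancestors(
    ontology: Ontology, concept_id: ConceptID, include_self: bool = False
) -> frozenset[ConceptID]:
    """Functional alias for :meth:`Ontology.ancestors`."""
    return ontology.ancestors(concept_id, include_self=include_self)


def validate_eq_definition(
    definition: EQDefinition, qualities: Ontology, entities: Ontology
) -> None:
    """Check that every conjunct resolves in the support ontologies."""
    bad = [
        cj.quality
        for cj in definition.conjuncts
        if cj.quality not in qualities
    ] + [cj.entity for cj in definition.conjuncts if cj.entity not in entities]
    if bad:
        raise ValidationError(
            f"{definition.concept}: unresolvable support IDs {sorted(set(bad))}"
        )
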