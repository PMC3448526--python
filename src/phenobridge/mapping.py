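"""Mapping construction: taxonomic propagation through a merged ontology.

Both alignment methods emit cross-ontology axioms (lexical seeds as
equivalences, EQ reasoning as subclass/equivalence axioms).  A mapping is
then obtained by merging both taxonomies with those axioms and reading off,
for every source concept, all reachable concepts of the target ontology —
its "equivalent and super concepts".  Reachability runs over child->parent
``is_a`` edges of both ontologies, sub->super edges for subclass axioms and
both directions for equivalences.  Mappings are direction-specific and in
general not symmetrical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .errors import ParseError, ValidationError
from .formal import MappingAxiom
from .lexical import SeedPair
from .ontology import ConceptID, Ontology


def seeds_to_axioms(pairs: Iterable[SeedPair]) -> set[MappingAxiom]:
    """Interpret lexical seed pairs as equivalence axioms."""
    return {
        MappingAxiom(kind="equivalent", sub=p.left, super=p.right) for p in pairs
    }


class MergedClosure:
    """Reachability oracle over two ontologies merged by cross axioms."""

    def __init__(
        self, o1: Ontology, o2: Ontology, axioms: Iterable[MappingAxiom]
    ) -> None:
        graph = nx.DiGraph()
        for o in (o1, o2):
            graph.add_nodes_from(o.active_ids())
            graph.add_edges_from(o.graph().edges())
        for ax in axioms:
            for endpoint in (ax.sub, ax.super):
                if endpoint not in graph:
                    raise ValidationError(
                        f"axiom endpoint {endpoint} is not an active concept "
                        "of either ontology"
                    )
            graph.add_edge(ax.sub, ax.super)
            if ax.kind == "equivalent":
                graph.add_edge(ax.super, ax.sub)
        self._graph = graph
        self._cache: dict[ConceptID, frozenset[ConceptID]] = {}

    def reach(self, concept_id: ConceptID) -> frozenset[ConceptID]:
        """All concepts reachable from ``concept_id`` (reflexive)."""
        cached = self._cache.get(concept_id)
        if cached is None:
            if concept_id not in self._graph:
                raise ValidationError(f"unknown concept {concept_id}")
            # equivalence axioms introduce 2-cycles, so plain DFS memoization
            # is unsound; networkx descendants handles the cyclic case
            cached = frozenset(nx.descendants(self._graph, concept_id)) | {
                concept_id
            }
            self._cache[concept_id] = cached
        return cached


def merge_and_close(
    o1: Ontology, o2: Ontology, axioms: Iterable[MappingAxiom]
) -> MergedClosure:
    """Merge two ontologies with cross axioms into a reachability oracle."""
    return MergedClosure(o1, o2, axioms)


@dataclass
class Mapping:
    """Direction-specific mapping: source concept -> set of target concepts.

    A concept with an empty propagated set is simply absent from
    ``entries`` ("not mapped").
    """

    source_prefix: str
    target_prefix: str
    method: str = "lexical"  # "lexical" or "formal"
    entries: dict[ConceptID, frozenset[ConceptID]] = field(default_factory=dict)

    def mapped_count(self) -> int:
        return len(self.entries)

    def average_mapped(self) -> float | None:
        """Mean target-set size over mapped concepts; None when unmapped."""
        if not self.entries:
            return None
        return sum(len(v) for v in self.entries.values()) / len(self.entries)


def build_mapping(
    o1: Ontology,
    o2: Ontology,
    axioms: Iterable[MappingAxiom],
    source_prefix: str,
    target_prefix: str,
    method: str = "lexical",
    drop_roots: bool = False,
    closure: MergedClosure | None = None,
) -> Mapping:
    """Propagate axioms and extract the source->target mapping.

    For every non-obsolete source concept the entry is the set of target
    concepts reachable in the merged graph; concepts reaching no target
    concept are omitted.  ``drop_roots`` removes target concepts that have
    no parents (ontology roots) from every entry; by default roots are
    retained.
    """
    prefixes = {o1.prefix, o2.prefix}
    if {source_prefix, target_prefix} != prefixes:
        raise ValidationError(
            f"direction {source_prefix}->{target_prefix} does not match "
            f"ontologies {sorted(prefixes)}"
        )
    source, target = (o1, o2) if source_prefix == o1.prefix else (o2, o1)
    if closure is None:
        closure = merge_and_close(o1, o2, axioms)
    target_ids = set(target.active_ids())
    if drop_roots:
        target_ids -= {
            cid for cid in target_ids if not target[cid].parent_ids
        }
    entries: dict[ConceptID, frozenset[ConceptID]] = {}
    for cid in source.active_ids():
        hit = closure.reach(cid) & target_ids
        if hit:
            entries[cid] = frozenset(hit)
    return Mapping(
        source_prefix=source_prefix,
        target_prefix=target_prefix,
        method=method,
        entries=entries,
    )


def write_mapping(mapping: Mapping) -> str:
    """One line per source concept: source ID then sorted target IDs.

    Matches the plain whitespace-separated record form, e.g.
    ``HP:0007062 MP:0000001 MP:0002106 ...``.
    """
    lines = []
    for cid in sorted(mapping.entries):
        targets = " ".join(sorted(mapping.entries[cid]))
        lines.append(f"{cid} {targets}\n")
    return "".join(lines)


def parse_mapping(
    text: str,
    source_prefix: str | None = None,
    target_prefix: str | None = None,
    method: str = "lexical",
) -> Mapping:
    """Parse the whitespace-separated mapping record format.

    Prefixes are inferred from the first record when not given.  Duplicate
    source lines merge their target sets.
    """
    entries: dict[ConceptID, set[ConceptID]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(
                f"line {lineno}: mapping record needs a source and at least "
                "one target ID"
            )
        entries.setdefault(tokens[0], set()).update(tokens[1:])
    if entries:
        first = next(iter(sorted(entries)))
        if source_prefix is None:
            source_prefix = first.split(":", 1)[0]
        if target_prefix is None:
            target_prefix = next(iter(sorted(entries[first]))).split(":", 1)[0]
    return Mapping(
        source_prefix=source_prefix or "",
        target_prefix=target_prefix or "",
        method=method,
        entries={k: frozenset(v) for k, v in entries.items()},
    )
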