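"""Shared fixtures: tiny hand-built ontologies and independent oracles.

The oracle helpers here recompute closures by naive path enumeration
directly from ``parent_ids`` so they stay independent of the package's
cached graph traversal.
"""

from __future__ import annotations

import numpy as np
import pytest

from phenobridge import Concept, EQConjunct, EQDefinition, Ontology


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_ancestors(
    ontology: Ontology, concept_id: str, include_self: bool = False
) -> set[str]:
    """All nodes on any upward parent path, by plain enumeration."""
    out: set[str] = set()
    stack = [concept_id]
    while stack:
        current = stack.pop()
        concept = ontology[current]
        if concept.obsolete:
            continue
        for p in concept.parent_ids:
            if p in ontology and p not in out:
                out.add(p)
                stack.append(p)
    if include_self:
        out.add(concept_id)
    return out


def brute_force_reachability(
    nodes: list[str], edges: set[tuple[str, str]]
) -> dict[str, set[str]]:
    """Floyd-Warshall style reflexive-transitive closure on a digraph."""
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for u, v in edges:
        reach[index[u], index[v]] = True
    for k in range(n):
        reach |= reach[:, k : k + 1] & reach[k : k + 1, :]
    return {
        u: {nodes[j] for j in np.flatnonzero(reach[i])}
        for u, i in index.items()
    }


def brute_force_eq_subsumes(
    d1: EQDefinition, d2: EQDefinition, qualities: Ontology, entities: Ontology
) -> bool:
    """Exhaustive conjunct-assignment check against path-enumeration closures."""

    def covers(x: EQConjunct, y: EQConjunct) -> bool:
        return y.quality in brute_force_ancestors(
            qualities, x.quality, include_self=True
        ) and y.entity in brute_force_ancestors(
            entities, x.entity, include_self=True
        )

    return all(any(covers(x, y) for x in d1.conjuncts) for y in d2.conjuncts)


def random_dag(
    rng: np.random.Generator, prefix: str, n: int, edge_prob: float = 0.15
) -> Ontology:
    """Random acyclic ontology: node i may have parents among nodes > i."""
    concepts = []
    for i in range(n):
        parents = [
            f"{prefix}:{j:07d}"
            for j in range(i + 1, n)
            if rng.random() < edge_prob
        ]
        concepts.append(
            Concept(id=f"{prefix}:{i:07d}", label=f"{prefix} node {i}",
                    parent_ids=parents)
        )
    return Ontology(prefix, concepts)


# ---------------------------------------------------------------------------
# hand-built fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def supports() -> tuple[Ontology, Ontology]:
    """Six-node quality and entity trees with known is_a chains.

    qualities: size <- {increased-size, decreased-size}; color <- red
    entities:  organ <- heart <- left-ventricle; organ <- kidney
    """
    qualities = Ontology(
        "QUA",
        [
            Concept(id="QUA:0000001", label="quality"),
            Concept(id="QUA:0000002", label="size", parent_ids=["QUA:0000001"]),
            Concept(
                id="QUA:0000003",
                label="increased size",
                parent_ids=["QUA:0000002"],
            ),
            Concept(
                id="QUA:0000004",
                label="decreased size",
                parent_ids=["QUA:0000002"],
            ),
            Concept(id="QUA:0000005", label="color", parent_ids=["QUA:0000001"]),
            Concept(id="QUA:0000006", label="red", parent_ids=["QUA:0000005"]),
        ],
    )
    entities = Ontology(
        "ENT",
        [
            Concept(id="ENT:0000001", label="organ"),
            Concept(id="ENT:0000002", label="heart", parent_ids=["ENT:0000001"]),
            Concept(
                id="ENT:0000003",
                label="left ventricle",
                parent_ids=["ENT:0000002"],
            ),
            Concept(id="ENT:0000004", label="kidney", parent_ids=["ENT:0000001"]),
        ],
    )
    return qualities, entities


@pytest.fixture
def diamond() -> Ontology:
    """c -> {b1, b2} -> a."""
    return Ontology(
        "HP",
        [
            Concept(id="HP:0000001", label="a"),
            Concept(id="HP:0000002", label="b1", parent_ids=["HP:0000001"]),
            Concept(id="HP:0000003", label="b2", parent_ids=["HP:0000001"]),
            Concept(
                id="HP:0000004",
                label="c",
                parent_ids=["HP:0000002", "HP:0000003"],
            ),
        ],
    )


def make_concepts(prefix: str, spec: dict[str, tuple[str, list[str]]]):
    """Helper: {local: (label, [parent locals])} -> list of Concepts."""
    return [
        Concept(
            id=f"{prefix}:{local}",
            label=label,
            parent_ids=[f"{prefix}:{p}" for p in parents],
        )
        for local, (label, parents) in spec.items()
    ]
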