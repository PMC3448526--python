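"""Lexical seeding of cross-ontology equivalences.

Two concepts from different ontologies are seeded as equivalent when any of
their normalized names or synonyms coincide exactly — the strict-matching
core of LOOM-style lexical alignment.  Normalization lowercases, maps
punctuation and hyphens to spaces and collapses whitespace; no stemming or
approximate matching is applied.  Seed pairs are later interpreted as
equivalence axioms and propagated through the merged taxonomy.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Iterable

from .errors import ParseError
from .ontology import ConceptID, Ontology, concept_prefix

#: Evidence channels ordered from strongest to weakest.
MATCH_KINDS = ("name-name", "name-synonym", "synonym-name", "synonym-synonym")


@dataclass(frozen=True, order=True)
class SeedPair:
    """An equivalence seed between one concept of each ontology."""

    left: ConceptID
    right: ConceptID
    matched_on: str = "name-name"

    def __post_init__(self) -> None:
        if concept_prefix(self.left) == concept_prefix(self.right):
            raise ValueError(
                f"seed pair within one ontology: {self.left} {self.right}"
            )
        if self.matched_on not in MATCH_KINDS:
            raise ValueError(f"unknown match kind: {self.matched_on}")


def normalize_label(s: str) -> str:
    """Normalize a label for exact comparison.

    Lowercases, replaces every Unicode punctuation character (hyphens
    included) with a space, collapses whitespace runs and strips the ends.
    """
    chars = [
        " " if unicodedata.category(ch).startswith("P") else ch
        for ch in s.lower()
    ]
    return " ".join("".join(chars).split())


def _term_strings(ontology: Ontology) -> dict[str, list[tuple[ConceptID, bool]]]:
    """Normalized string -> [(concept, is_name)] over active concepts."""
    pool: dict[str, list[tuple[ConceptID, bool]]] = {}
    for cid in ontology.active_ids():
        concept = ontology[cid]
        entries = [(concept.label, True)] + [(s, False) for s in concept.synonyms]
        for text, is_name in entries:
            norm = normalize_label(text)
            if norm:
                pool.setdefault(norm, []).append((cid, is_name))
    return pool


def lexical_seed_pairs(o1: Ontology, o2: Ontology) -> set[SeedPair]:
    """All cross-ontology pairs sharing a normalized name or synonym.

    A pair is emitted at most once; ``matched_on`` records the strongest
    evidence found (name-name > name-synonym > synonym-name >
    synonym-synonym).  Many-to-many seeds are allowed.  Obsolete concepts
    never match.
    """
    pool1 = _term_strings(o1)
    pool2 = _term_strings(o2)
    best: dict[tuple[ConceptID, ConceptID], int] = {}
    for norm, hits1 in pool1.items():
        hits2 = pool2.get(norm)
        if not hits2:
            continue
        for left, left_is_name in hits1:
            for right, right_is_name in hits2:
                rank = MATCH_KINDS.index(
                    f"{'name' if left_is_name else 'synonym'}-"
                    f"{'name' if right_is_name else 'synonym'}"
                )
                key = (left, right)
                if key not in best or rank < best[key]:
                    best[key] = rank
    return {
        SeedPair(left=l, right=r, matched_on=MATCH_KINDS[rank])
        for (l, r), rank in best.items()
    }


def write_seed_pairs(pairs: Iterable[SeedPair]) -> str:
    """TSV serialization: ``left_id<TAB>right_id<TAB>matched_on``."""
    return "".join(
        f"{p.left}\t{p.right}\t{p.matched_on}\n" for p in sorted(pairs)
    )


def parse_seed_pairs(text: str) -> set[SeedPair]:
    """Read seed pairs from TSV or the two-column space-separated form."""
    pairs: set[SeedPair] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        tokens = line.replace("\t", " ").split()
        if len(tokens) < 2:
            raise ParseError(f"line {lineno}: expected at least two IDs")
        matched_on = tokens[2] if len(tokens) > 2 else "name-name"
        pairs.add(SeedPair(left=tokens[0], right=tokens[1], matched_on=matched_on))
    return pairs
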