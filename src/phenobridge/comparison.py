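"""Five-way overlap classification of two mappings for the same direction.

For every source concept mapped by *both* methods, the two target sets are
compared and filed into exactly one of five categories:

* ``exact`` — identical target sets;
* ``lexical_subset_of_formal`` — lexical targets a proper subset of formal;
* ``formal_subset_of_lexical`` — the converse proper subset;
* ``overlap`` — a non-empty intersection without containment either way;
* ``nothing`` — disjoint target sets.

The categories partition the doubly-mapped concepts, so the per-category
counts always sum to the number of compared concepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UsageError
from .mapping import Mapping
from .ontology import ConceptID

CATEGORIES = (
    "exact",
    "lexical_subset_of_formal",
    "formal_subset_of_lexical",
    "overlap",
    "nothing",
)


def classify_overlap(
    lexical: frozenset[ConceptID] | set[ConceptID],
    formal: frozenset[ConceptID] | set[ConceptID],
) -> str:
    """Classify one pair of non-empty target sets into the five categories."""
    if not lexical or not formal:
        raise UsageError(
            "classify_overlap requires non-empty sets; pre-filter concepts "
            "mapped by only one method"
        )
    if lexical == formal:
        return "exact"
    if lexical < formal:
        return "lexical_subset_of_formal"
    if formal < lexical:
        return "formal_subset_of_lexical"
    if lexical & formal:
        return "overlap"
    return "nothing"


@dataclass(frozen=True)
class OverlapRecord:
    concept: ConceptID
    category: str
    lexical_size: int
    formal_size: int
    intersection_size: int


@dataclass
class OverlapTable:
    """Per-direction category counts over doubly-mapped concepts."""

    source_prefix: str
    target_prefix: str
    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CATEGORIES}
    )
    total: int = 0


def compare_mappings(
    lexical: Mapping, formal: Mapping
) -> tuple[OverlapTable, list[OverlapRecord]]:
    """Compare two same-direction mappings concept by concept.

    Only concepts present in both mappings are classified; concepts mapped
    by a single method are coverage-only and reported elsewhere.
    """
    if (lexical.source_prefix, lexical.target_prefix) != (
        formal.source_prefix,
        formal.target_prefix,
    ):
        raise UsageError(
            "mappings have different directions: "
            f"{lexical.source_prefix}->{lexical.target_prefix} vs "
            f"{formal.source_prefix}->{formal.target_prefix}"
        )
    table = OverlapTable(
        source_prefix=lexical.source_prefix, target_prefix=lexical.target_prefix
    )
    records: list[OverlapRecord] = []
    for concept in sorted(set(lexical.entries) & set(formal.entries)):
        lset = lexical.entries[concept]
        fset = formal.entries[concept]
        category = classify_overlap(lset, fset)
        records.append(
            OverlapRecord(
                concept=concept,
                category=category,
                lexical_size=len(lset),
                formal_size=len(fset),
                intersection_size=len(lset & fset),
            )
        )
        table.counts[category] += 1
        table.total += 1
    return table, records


def write_overlap_table(tables: list[OverlapTable]) -> str:
    """TSV report: one row per category plus a total row, one column per
    direction."""
    header = "category\t" + "\t".join(
        f"{t.source_prefix}_to_{t.target_prefix}" for t in tables
    )
    lines = [header]
    for cat in CATEGORIES:
        lines.append(cat + "\t" + "\t".join(str(t.counts[cat]) for t in tables))
    lines.append("total\t" + "\t".join(str(t.total) for t in tables))
    return "\n".join(lines) + "\n"


def write_overlap_records(records: list[OverlapRecord]) -> str:
    """Audit TSV: per-concept category and set sizes."""
    lines = ["concept\tcategory\tlexical_size\tformal_size\tintersection_size"]
    for r in records:
        lines.append(
            f"{r.concept}\t{r.category}\t{r.lexical_size}\t{r.formal_size}"
            f"\t{r.intersection_size}"
        )
    return "\n".join(lines) + "\n"
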