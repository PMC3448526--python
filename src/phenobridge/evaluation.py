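"""Gene-disease prioritization as a mapping quality benchmark.

Disease phenotype profiles (one ontology) and mouse-model profiles (the
other) are brought into a common concept space by translating one side
through a mapping, scored with the cosine similarity between their binary
concept vectors,

    sim(A, B) = |A ∩ B| / (sqrt(|A|) * sqrt(|B|)),

and every (disease, model) combination is pooled into a single ranking.
Pairs whose model gene has a human ortholog associated with the disease in
the gold standard count as positives; all other pairs are negatives.  The
pooled ranking yields one ROC curve and AUC per (mapping method, translation
scenario).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping as TMapping, Sequence

from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .errors import EvaluationError, ParseError, UsageError
from .mapping import Mapping
from .ontology import ConceptID, Ontology

#: Translation scenarios: which side is rewritten into the other's ontology.
SCENARIOS = ("disease_to_model_space", "model_to_disease_space")


@dataclass
class AnnotationSet:
    """Phenotype profile of one disease or mouse model.

    ``gene`` is set for mouse models only (one gene per model).
    """

    owner: str
    concepts: frozenset[ConceptID]
    gene: str | None = None


@dataclass(frozen=True)
class RankedPair:
    disease: str
    model: str
    gene: str
    similarity: float
    positive: bool


@dataclass
class ROCResult:
    points: list[tuple[float, float]]
    auc: float


def translate(s: AnnotationSet, m: Mapping) -> frozenset[ConceptID]:
    """Rewrite an annotation set into the mapping's target ontology.

    The result is the union of the mapped target sets of the annotations;
    unmapped annotations contribute nothing, so the result may be empty.
    """
    prefixes = {c.split(":", 1)[0] for c in s.concepts}
    if prefixes - {m.source_prefix}:
        raise UsageError(
            f"annotation prefixes {sorted(prefixes)} do not match mapping "
            f"source {m.source_prefix!r}"
        )
    out: set[ConceptID] = set()
    for c in s.concepts:
        out |= m.entries.get(c, frozenset())
    return frozenset(out)


def cosine_similarity(
    a: Iterable[ConceptID], b: Iterable[ConceptID]
) -> float:
    """Cosine of the binary indicator vectors of two concept sets.

    Equals ``|a ∩ b| / (sqrt(|a|) * sqrt(|b|))``; zero when either set is
    empty (the cosine is undefined for zero vectors).
    """
    sa, sb = set(a), set(b)
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / math.sqrt(len(sa) * len(sb))


def close_annotations(s: AnnotationSet, ontology: Ontology) -> AnnotationSet:
    """Reflexive ancestor closure of a profile (sensitivity analysis)."""
    closed: set[ConceptID] = set()
    for c in s.concepts:
        closed |= ontology.ancestors(c, include_self=True)
    return AnnotationSet(owner=s.owner, concepts=frozenset(closed), gene=s.gene)


def rank_pairs(
    diseases: Sequence[AnnotationSet],
    models: Sequence[AnnotationSet],
    m: Mapping,
    scenario: str,
    orthology: TMapping[str, str],
    gold: set[tuple[str, str]],
) -> list[RankedPair]:
    """Score and rank every (disease, model) combination.

    ``scenario`` picks which side is translated: diseases are translated
    into model space for ``disease_to_model_space``, models into disease
    space for the converse.  The mapping's direction must agree.  A model
    gene without a human ortholog makes all its pairs negative.  The result
    is sorted by similarity descending, ties broken by (disease, model) ID.
    """
    if scenario not in SCENARIOS:
        raise UsageError(f"unknown scenario: {scenario}")
    for model in models:
        if model.gene is None:
            raise UsageError(f"model {model.owner} has no gene")
    if scenario == "disease_to_model_space":
        disease_sets = {d.owner: translate(d, m) for d in diseases}
        model_sets = {mm.owner: mm.concepts for mm in models}
    else:
        disease_sets = {d.owner: d.concepts for d in diseases}
        model_sets = {mm.owner: translate(mm, m) for mm in models}
    pairs: list[RankedPair] = []
    for d in diseases:
        for mm in models:
            human_gene = orthology.get(mm.gene)
            positive = (
                human_gene is not None and (human_gene, d.owner) in gold
            )
            pairs.append(
                RankedPair(
                    disease=d.owner,
                    model=mm.owner,
                    gene=mm.gene,
                    similarity=cosine_similarity(
                        disease_sets[d.owner], model_sets[mm.owner]
                    ),
                    positive=positive,
                )
            )
    pairs.sort(key=lambda p: (-p.similarity, p.disease, p.model))
    return pairs


def roc_and_auc(pairs: Sequence[RankedPair]) -> ROCResult:
    """Pooled single-ranking ROC with block tie handling; trapezoidal AUC.

    Raises :class:`EvaluationError` unless both a positive and a negative
    pair are present.
    """
    labels = [int(p.positive) for p in pairs]
    scores = [p.similarity for p in pairs]
    if len(set(labels)) < 2:
        raise EvaluationError(
            "ROC needs at least one positive and one negative pair"
        )
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(
        points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=float(_trapezoid_auc(fpr, tpr)),
    )


# ---------------------------------------------------------------------------
# plain-text IO for the annotation corpus
# ---------------------------------------------------------------------------


def parse_model_annotations(text: str) -> list[AnnotationSet]:
    """``model_id<TAB>gene_id<TAB>concept_id`` rows, one per annotation."""
    rows: dict[str, tuple[str, set[ConceptID]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        tokens = line.rstrip("\n").split("\t")
        if len(tokens) != 3:
            raise ParseError(f"line {lineno}: expected model<TAB>gene<TAB>concept")
        model, gene, concept = tokens
        entry = rows.setdefault(model, (gene, set()))
        if entry[0] != gene:
            raise ParseError(
                f"line {lineno}: model {model} listed with two genes"
            )
        entry[1].add(concept)
    return [
        AnnotationSet(owner=model, concepts=frozenset(cs), gene=gene)
        for model, (gene, cs) in rows.items()
    ]


def write_model_annotations(models: Sequence[AnnotationSet]) -> str:
    lines = []
    for m in sorted(models, key=lambda s: s.owner):
        for c in sorted(m.concepts):
            lines.append(f"{m.owner}\t{m.gene}\t{c}\n")
    return "".join(lines)


def parse_disease_annotations(text: str) -> list[AnnotationSet]:
    """``disease_id<TAB>concept_id`` rows, one per annotation."""
    rows: dict[str, set[ConceptID]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        tokens = line.rstrip("\n").split("\t")
        if len(tokens) != 2:
            raise ParseError(f"line {lineno}: expected disease<TAB>concept")
        rows.setdefault(tokens[0], set()).add(tokens[1])
    return [
        AnnotationSet(owner=d, concepts=frozenset(cs))
        for d, cs in rows.items()
    ]


def write_disease_annotations(diseases: Sequence[AnnotationSet]) -> str:
    lines = []
    for d in sorted(diseases, key=lambda s: s.owner):
        for c in sorted(d.concepts):
            lines.append(f"{d.owner}\t{c}\n")
    return "".join(lines)


def parse_two_column(text: str) -> dict[str, str]:
    """Generic two-column TSV (orthology: mouse gene -> human gene)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        tokens = line.rstrip("\n").split("\t")
        if len(tokens) != 2:
            raise ParseError(f"line {lineno}: expected two columns")
        out[tokens[0]] = tokens[1]
    return out


def parse_gold(text: str) -> set[tuple[str, str]]:
    """``human_gene<TAB>disease_id`` gold association rows."""
    gold: set[tuple[str, str]] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        tokens = line.rstrip("\n").split("\t")
        if len(tokens) != 2:
            raise ParseError(f"line {lineno}: expected gene<TAB>disease")
        gold.add((tokens[0], tokens[1]))
    return gold


def write_gold(gold: set[tuple[str, str]]) -> str:
    return "".join(f"{g}\t{d}\n" for g, d in sorted(gold))


def write_orthology(orthology: TMapping[str, str]) -> str:
    return "".join(f"{m}\t{h}\n" for m, h in sorted(orthology.items()))


def write_ranked_pairs(pairs: Sequence[RankedPair]) -> str:
    lines = ["disease\tmodel\tgene\tsimilarity\tpositive"]
    for p in pairs:
        lines.append(
            f"{p.disease}\t{p.model}\t{p.gene}\t{p.similarity:.6f}"
            f"\t{int(p.positive)}"
        )
    return "\n".join(lines) + "\n"


def write_roc_points(result: ROCResult) -> str:
    lines = ["fpr\ttpr"]
    for fpr, tpr in result.points:
        lines.append(f"{fpr:.6f}\t{tpr:.6f}")
    return "\n".join(lines) + "\n"
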