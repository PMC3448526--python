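"""End-to-end orchestration: generate, align, map, compare, evaluate.

``run_all`` runs the whole study on a generated bundle and returns a
:class:`RunReport` mirroring the summary artifacts of an alignment study:
per-method mapped-concept counts with coverage percentages and mean
mapped-set sizes, the five-category overlap tables per direction, and the
ROC AUC per (method, translation scenario).  All derived percentages and
averages are recomputable from the report's own raw counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

from . import comparison, evaluation, formal, lexical, mapping, synthetic
from .errors import EvaluationError
from .mapping import Mapping
from .ontology import Ontology

logger = logging.getLogger(__name__)

METHODS = ("lexical", "formal")
DIRECTIONS = ("1to2", "2to1")


def pct(part: int, total: int) -> float:
    """Percentage rounded half-up to two decimals (presentation rule)."""
    if total == 0:
        return 0.0
    value = Decimal(100 * part) / Decimal(total)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def round2(value: float) -> float:
    return float(
        Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


@dataclass
class CoverageRow:
    """One mapping's coverage summary (a generated-mapping table row)."""

    ontology: str
    method: str
    total_concepts: int
    defined_concepts: int
    mapped_concepts: int
    pct_mapped: float
    avg_mapped: float | None  # None rendered as "-" when nothing is mapped


def table1_stats(
    mappings: Sequence[Mapping],
    ontologies: dict[str, Ontology],
    defined_counts: dict[str, int],
) -> list[CoverageRow]:
    """Coverage rows for a set of mappings, one row per mapping."""
    rows = []
    for m in mappings:
        total = len(ontologies[m.source_prefix].active_ids())
        avg = m.average_mapped()
        rows.append(
            CoverageRow(
                ontology=m.source_prefix,
                method=m.method,
                total_concepts=total,
                defined_concepts=defined_counts.get(m.source_prefix, 0),
                mapped_concepts=m.mapped_count(),
                pct_mapped=pct(m.mapped_count(), total),
                avg_mapped=None if avg is None else round2(avg),
            )
        )
    return rows


@dataclass
class RunReport:
    config: dict
    seed: int
    coverage: list[CoverageRow]
    overlap: dict[str, comparison.OverlapTable]
    auc: dict[str, float | None]  # keyed "<method>_<scenario>"
    skipped: dict[str, int]

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "coverage": [dataclasses.asdict(r) for r in self.coverage],
            "overlap": {
                k: {"counts": t.counts, "total": t.total}
                for k, t in self.overlap.items()
            },
            "auc": self.auc,
            "skipped": self.skipped,
        }
        return json.dumps(payload, indent=2) + "\n"


def build_all_mappings(
    bundle: synthetic.Bundle, drop_roots: bool = False
) -> dict[tuple[str, str], Mapping]:
    """The four mappings: (method, direction) -> Mapping."""
    sp = bundle.species
    seeds = lexical.lexical_seed_pairs(sp.o1, sp.o2)
    lex_axioms = mapping.seeds_to_axioms(seeds)
    frm_axioms = formal.formal_axioms(
        sp.defs1, sp.defs2, bundle.qualities, bundle.entities
    )
    out: dict[tuple[str, str], Mapping] = {}
    for method, axioms in (("lexical", lex_axioms), ("formal", frm_axioms)):
        closure = mapping.merge_and_close(sp.o1, sp.o2, axioms)
        for direction in DIRECTIONS:
            src, tgt = (
                (sp.o1.prefix, sp.o2.prefix)
                if direction == "1to2"
                else (sp.o2.prefix, sp.o1.prefix)
            )
            out[(method, direction)] = mapping.build_mapping(
                sp.o1,
                sp.o2,
                axioms,
                source_prefix=src,
                target_prefix=tgt,
                method=method,
                drop_roots=drop_roots,
                closure=closure,
            )
    return out


def evaluate_bundle(
    bundle: synthetic.Bundle,
    mappings: dict[tuple[str, str], Mapping],
    close_annotations: bool = False,
) -> dict[str, float | None]:
    """AUC per (method, scenario); None when ROC is undefined."""
    sp = bundle.species
    diseases = bundle.diseases
    models = bundle.models
    if close_annotations:
        diseases = [evaluation.close_annotations(d, sp.o1) for d in diseases]
        models = [evaluation.close_annotations(m, sp.o2) for m in models]
    aucs: dict[str, float | None] = {}
    for method in METHODS:
        for scenario, direction in (
            ("disease_to_model_space", "1to2"),
            ("model_to_disease_space", "2to1"),
        ):
            pairs = evaluation.rank_pairs(
                diseases,
                models,
                mappings[(method, direction)],
                scenario=scenario,
                orthology=bundle.orthology,
                gold=bundle.gold,
            )
            try:
                aucs[f"{method}_{scenario}"] = evaluation.roc_and_auc(pairs).auc
            except EvaluationError:
                logger.warning(
                    "%s/%s: ROC undefined (missing positives or negatives)",
                    method,
                    scenario,
                )
                aucs[f"{method}_{scenario}"] = None
    return aucs


def run_all(
    cfg: synthetic.GeneratorConfig,
    outdir: str | Path | None = None,
    drop_roots: bool = False,
    close_annotations: bool = False,
) -> RunReport:
    """Run the whole pipeline on a freshly generated bundle.

    Deterministic for a fixed config; writes the bundle, intermediate
    mapping/overlap/ROC files and the JSON report when ``outdir`` is given.
    """
    bundle = synthetic.generate_bundle(cfg)
    mappings = build_all_mappings(bundle, drop_roots=drop_roots)
    sp = bundle.species
    defined_counts = {
        sp.o1.prefix: len(sp.defs1),
        sp.o2.prefix: len(sp.defs2),
    }
    coverage = table1_stats(
        [mappings[k] for k in sorted(mappings)],
        {sp.o1.prefix: sp.o1, sp.o2.prefix: sp.o2},
        defined_counts,
    )
    overlap_tables: dict[str, comparison.OverlapTable] = {}
    records_by_direction = {}
    for direction in DIRECTIONS:
        table, records = comparison.compare_mappings(
            mappings[("lexical", direction)], mappings[("formal", direction)]
        )
        overlap_tables[direction] = table
        records_by_direction[direction] = records
    aucs = evaluate_bundle(
        bundle, mappings, close_annotations=close_annotations
    )
    n_obsolete = sum(
        len(o) - len(o.active_ids()) for o in (sp.o1, sp.o2)
    )
    report = RunReport(
        config=dataclasses.asdict(cfg),
        seed=cfg.seed,
        coverage=coverage,
        overlap=overlap_tables,
        auc=aucs,
        skipped={
            "obsolete_concepts": n_obsolete,
            "undefined_concepts_1": len(sp.o1.active_ids()) - 1 - len(sp.defs1),
            "undefined_concepts_2": len(sp.o2.active_ids()) - 1 - len(sp.defs2),
        },
    )
    if outdir is not None:
        outdir = Path(outdir)
        synthetic.write_bundle(bundle, outdir / "inputs")
        for (method, direction), m in sorted(mappings.items()):
            path = outdir / f"mapping_{method}_{direction}.txt"
            path.write_text(mapping.write_mapping(m))
        (outdir / "overlap_tables.tsv").write_text(
            comparison.write_overlap_table(
                [overlap_tables[d] for d in DIRECTIONS]
            )
        )
        for direction in DIRECTIONS:
            (outdir / f"overlap_records_{direction}.tsv").write_text(
                comparison.write_overlap_records(records_by_direction[direction])
            )
        (outdir / "report.json").write_text(report.to_json())
    return report
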