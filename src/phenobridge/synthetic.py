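"""Seeded generator for a complete toy cross-species phenotype study.

The generator emulates the input bundle of a two-ontology alignment study:
shared entity/anatomy and quality support ontologies (UBERON/PATO roles), a
pair of species phenotype ontologies with EQ definitions and partially
shared labels (HP/MP roles), mouse-model and disease annotation corpora, a
1:1 orthology map and a gold set of planted gene-disease associations.

Construction principles
-----------------------
* Both species ontologies are built over the *same* sampled set of
  (quality, entity) pairs, so every concept has an identical-EQ partner in
  the other species (parallel local IDs).  ``is_a`` edges are asserted
  exactly where EQ subsumption holds between the sampled pairs, plus a
  species root, which makes the formal aligner's output predictable from
  construction.
* Definition coverage is a per-species fraction; the smaller defined set is
  nested inside the larger one, emulating a single cross-species
  definition effort consumed at different depths of completion.
* Label sharing and definition coverage can be biased by concept depth:
  positive ``label_depth_bias`` concentrates shared labels on specific
  (deep) concepts while positive ``definition_depth_bias`` concentrates
  definitions on general (shallow) concepts — the regime in which lexical
  matching aligns fewer but more specific concepts than EQ reasoning.
* Disease profiles of planted (gene, disease) associations are the
  identical-EQ counterparts of the gene's model profile, with a
  configurable fraction resampled as noise; unrelated diseases are
  annotated uniformly at random.

All randomness flows from one ``numpy`` generator seeded by the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import obo
from .errors import ConfigError
from .evaluation import (
    AnnotationSet,
    write_disease_annotations,
    write_gold,
    write_model_annotations,
    write_orthology,
)
from .ontology import Concept, ConceptID, EQConjunct, EQDefinition, Ontology

ENTITY_PREFIX = "ENT"
QUALITY_PREFIX = "QUA"
SPECIES1_PREFIX = "HPS"  # human-phenotype-like (synthetic)
SPECIES2_PREFIX = "MPS"  # mammalian-phenotype-like (synthetic)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study, with small-preset defaults."""

    seed: int = 0
    entity_depth: int = 3
    entity_branching: int = 3
    quality_depth: int = 3
    quality_branching: int = 3
    n_concepts_per_species: int = 200
    frac_defined_1: float = 1.0
    frac_defined_2: float = 1.0
    frac_shared_labels: float = 1.0
    definition_depth_bias: float = 0.0
    label_depth_bias: float = 0.0
    n_genes: int = 15
    n_models: int = 15
    n_diseases: int = 15
    annotations_per_entity: tuple[int, int] = (5, 7)
    n_true_associations: int = 10
    annotation_noise: float = 0.0

    def validate(self) -> None:
        for name in (
            "frac_defined_1",
            "frac_defined_2",
            "frac_shared_labels",
            "annotation_noise",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in (
            "entity_depth",
            "entity_branching",
            "quality_depth",
            "quality_branching",
            "n_concepts_per_species",
            "n_genes",
            "n_models",
            "n_diseases",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        lo, hi = self.annotations_per_entity
        if not 1 <= lo <= hi:
            raise ConfigError("annotations_per_entity must satisfy 1 <= lo <= hi")
        if self.n_true_associations > min(self.n_diseases, self.n_genes):
            raise ConfigError(
                "n_true_associations exceeds the number of diseases or genes"
            )
        if self.n_models < self.n_genes:
            raise ConfigError("n_models must be >= n_genes (one model per gene)")
        n_pairs = self._tree_size(self.entity_depth, self.entity_branching) * (
            self._tree_size(self.quality_depth, self.quality_branching)
        ) - 1
        if n_pairs < self.n_concepts_per_species - 1:
            raise ConfigError(
                f"support trees yield only {n_pairs} distinct (quality, entity) "
                f"pairs; need {self.n_concepts_per_species - 1}"
            )
        if hi >= self.n_concepts_per_species - 1:
            raise ConfigError("annotations_per_entity exceeds concept count")

    @staticmethod
    def _tree_size(depth: int, branching: int) -> int:
        if branching == 1:
            return depth + 1
        return (branching ** (depth + 1) - 1) // (branching - 1)


def small_preset(seed: int = 0, **overrides) -> GeneratorConfig:
    """Fully shared labels/definitions, noiseless planted associations."""
    return dataclasses.replace(GeneratorConfig(seed=seed), **overrides)


def paper_shaped_preset(seed: int = 0, **overrides) -> GeneratorConfig:
    """Partial, depth-biased coverage shaped like the real HP/MP study:
    definition coverage near 48%/63%, sparse deep label sharing."""
    cfg = GeneratorConfig(
        seed=seed,
        n_concepts_per_species=300,
        frac_defined_1=0.48,
        frac_defined_2=0.63,
        frac_shared_labels=0.25,
        definition_depth_bias=0.8,
        label_depth_bias=0.8,
        n_genes=20,
        n_models=20,
        n_diseases=20,
        n_true_associations=12,
        annotation_noise=0.2,
    )
    return dataclasses.replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# support ontologies
# ---------------------------------------------------------------------------


def _make_tree(
    prefix: str, depth: int, branching: int, root_label: str, node_label: str
) -> Ontology:
    """Complete rooted tree of the given depth and branching factor."""
    concepts = [Concept(id=f"{prefix}:{0:07d}", label=root_label)]
    level = [concepts[0].id]
    counter = 1
    for _ in range(depth):
        nxt: list[ConceptID] = []
        for parent in level:
            for _ in range(branching):
                cid = f"{prefix}:{counter:07d}"
                concepts.append(
                    Concept(
                        id=cid,
                        label=f"{node_label} {counter}",
                        parent_ids=[parent],
                    )
                )
                nxt.append(cid)
                counter += 1
        level = nxt
    return Ontology(prefix, concepts, name=root_label)


def generate_support_ontologies(cfg: GeneratorConfig) -> tuple[Ontology, Ontology]:
    """Entity (anatomy-like) and quality (PATO-like) support trees."""
    cfg.validate()
    entities = _make_tree(
        ENTITY_PREFIX,
        cfg.entity_depth,
        cfg.entity_branching,
        "anatomical entity",
        "part",
    )
    qualities = _make_tree(
        QUALITY_PREFIX,
        cfg.quality_depth,
        cfg.quality_branching,
        "quality",
        "quality",
    )
    return entities, qualities


# ---------------------------------------------------------------------------
# species pair
# ---------------------------------------------------------------------------


def _depths(ontology: Ontology) -> dict[ConceptID, int]:
    return {cid: len(ontology.ancestors(cid)) for cid in ontology}


def _weighted_sample(
    rng: np.random.Generator, items: np.ndarray, k: int, weights: np.ndarray
) -> np.ndarray:
    if k <= 0:
        return items[:0]
    p = weights / weights.sum()
    return rng.choice(items, size=k, replace=False, p=p)


@dataclass
class SpeciesPair:
    """Both species ontologies plus generator bookkeeping."""

    o1: Ontology
    defs1: dict[ConceptID, EQDefinition]
    o2: Ontology
    defs2: dict[ConceptID, EQDefinition]
    #: full EQ assignment per species concept (including withheld ones)
    eq_of: dict[ConceptID, EQConjunct] = field(default_factory=dict)

    def partner(self, concept_id: ConceptID) -> ConceptID:
        """Identical-EQ counterpart in the other species (parallel IDs)."""
        prefix, local = concept_id.split(":", 1)
        other = SPECIES2_PREFIX if prefix == SPECIES1_PREFIX else SPECIES1_PREFIX
        return f"{other}:{local}"


def generate_species_pair(
    cfg: GeneratorConfig,
    supports: tuple[Ontology, Ontology],
    rng: np.random.Generator | None = None,
) -> SpeciesPair:
    """Sample the shared EQ pool and build both species ontologies."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    entities, qualities = supports
    e_ids = sorted(entities)
    q_ids = sorted(qualities)
    e_depth = _depths(entities)
    q_depth = _depths(qualities)
    e_root, q_root = e_ids[0], q_ids[0]

    pool = [
        (q, e) for q in q_ids for e in e_ids if (q, e) != (q_root, e_root)
    ]
    n = cfg.n_concepts_per_species - 1  # one slot goes to the species root
    idx = rng.choice(len(pool), size=n, replace=False)
    pairs = [pool[i] for i in sorted(idx)]
    depths = np.array(
        [q_depth[q] + e_depth[e] for q, e in pairs], dtype=float
    )

    # nested defined index sets: the smaller coverage is a subset of the larger
    def_weights = np.exp(-cfg.definition_depth_bias * depths)
    k1 = round(cfg.frac_defined_1 * n)
    k2 = round(cfg.frac_defined_2 * n)
    all_idx = np.arange(n)
    big_k, small_k = max(k1, k2), min(k1, k2)
    big_set = _weighted_sample(rng, all_idx, big_k, def_weights)
    if small_k:
        small_set = _weighted_sample(
            rng, np.sort(big_set), small_k, def_weights[np.sort(big_set)]
        )
    else:
        small_set = all_idx[:0]
    defined1 = set((big_set if k1 >= k2 else small_set).tolist())
    defined2 = set((big_set if k2 > k1 else small_set).tolist())

    # shared-label index set, optionally biased toward deep concepts
    label_weights = np.exp(cfg.label_depth_bias * depths)
    shared = set(
        _weighted_sample(
            rng, all_idx, round(cfg.frac_shared_labels * n), label_weights
        ).tolist()
    )
    # evidence channel per shared label: mostly name-name, sometimes synonyms
    channel = rng.random(n)

    # subsumption structure over the sampled pairs (shared by both species)
    q_anc = {q: qualities.ancestors(q, include_self=True) for q in q_ids}
    e_anc = {e: entities.ancestors(e, include_self=True) for e in e_ids}
    parents: list[list[int]] = [[] for _ in range(n)]
    for i, (qi, ei) in enumerate(pairs):
        for j, (qj, ej) in enumerate(pairs):
            if i != j and qj in q_anc[qi] and ej in e_anc[ei]:
                parents[i].append(j)

    def build_species(
        prefix: str, species_tag: str
    ) -> tuple[Ontology, dict[ConceptID, EQConjunct]]:
        root_id = f"{prefix}:{0:07d}"
        concepts = [Concept(id=root_id, label=f"{species_tag} phenotype root")]
        eq_of: dict[ConceptID, EQConjunct] = {}
        for i, (q, e) in enumerate(pairs):
            cid = f"{prefix}:{i + 1:07d}"
            shared_label = (
                f"abnormal {entities[e].label} {qualities[q].label}"
            )
            own_label = f"{species_tag} phenotype {i + 1}"
            synonyms: list[str] = []
            if i in shared:
                u = channel[i]
                put_in_synonym = (
                    u >= 0.85 if prefix == SPECIES1_PREFIX else 0.7 <= u < 0.85
                )
                if put_in_synonym:
                    label, synonyms = own_label, [shared_label]
                else:
                    label = shared_label
            else:
                label = own_label
            parent_ids = [f"{prefix}:{j + 1:07d}" for j in parents[i]]
            if not parent_ids:
                parent_ids = [root_id]
            concepts.append(
                Concept(
                    id=cid, label=label, synonyms=synonyms, parent_ids=parent_ids
                )
            )
            eq_of[cid] = EQConjunct(quality=q, entity=e)
        return Ontology(prefix, concepts, name=f"{species_tag} phenotypes"), eq_of

    o1, eq1 = build_species(SPECIES1_PREFIX, "species one")
    o2, eq2 = build_species(SPECIES2_PREFIX, "species two")

    def defs_for(
        prefix: str, eq_of: dict[ConceptID, EQConjunct], defined: set[int]
    ) -> dict[ConceptID, EQDefinition]:
        return {
            f"{prefix}:{i + 1:07d}": EQDefinition(
                concept=f"{prefix}:{i + 1:07d}",
                conjuncts=(eq_of[f"{prefix}:{i + 1:07d}"],),
            )
            for i in sorted(defined)
        }

    return SpeciesPair(
        o1=o1,
        defs1=defs_for(SPECIES1_PREFIX, eq1, defined1),
        o2=o2,
        defs2=defs_for(SPECIES2_PREFIX, eq2, defined2),
        eq_of={**eq1, **eq2},
    )


# ---------------------------------------------------------------------------
# annotation corpus
# ---------------------------------------------------------------------------


@dataclass
class Bundle:
    """The complete generated study: ontologies, corpus and gold standard."""

    cfg: GeneratorConfig
    entities: Ontology
    qualities: Ontology
    species: SpeciesPair
    models: list[AnnotationSet]
    diseases: list[AnnotationSet]
    orthology: dict[str, str]
    gold: set[tuple[str, str]]


def generate_annotation_corpus(
    cfg: GeneratorConfig,
    species: SpeciesPair,
    rng: np.random.Generator | None = None,
) -> tuple[list[AnnotationSet], list[AnnotationSet], dict[str, str], set[tuple[str, str]]]:
    """Models (species-2 space), diseases (species-1 space), orthology, gold.

    Each model carries one mouse gene; planted (gene, disease) pairs give
    the disease the identical-EQ counterparts of the gene's first model's
    annotations, with ``annotation_noise`` of them resampled uniformly.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = cfg.annotations_per_entity
    o1_pool = sorted(set(species.o1.active_ids()) - {f"{SPECIES1_PREFIX}:{0:07d}"})
    o2_pool = sorted(set(species.o2.active_ids()) - {f"{SPECIES2_PREFIX}:{0:07d}"})

    models: list[AnnotationSet] = []
    for m in range(cfg.n_models):
        gene = f"MG:{m % cfg.n_genes:04d}"
        k = int(rng.integers(lo, hi + 1))
        concepts = rng.choice(len(o2_pool), size=k, replace=False)
        models.append(
            AnnotationSet(
                owner=f"MOD:{m:04d}",
                concepts=frozenset(o2_pool[i] for i in concepts),
                gene=gene,
            )
        )

    orthology = {f"MG:{g:04d}": f"HG:{g:04d}" for g in range(cfg.n_genes)}

    true_genes = rng.choice(cfg.n_genes, size=cfg.n_true_associations, replace=False)
    true_diseases = rng.choice(
        cfg.n_diseases, size=cfg.n_true_associations, replace=False
    )
    planted = {
        f"DIS:{int(d):04d}": int(g) for g, d in zip(true_genes, true_diseases)
    }
    gold = {
        (f"HG:{g:04d}", disease) for disease, g in sorted(planted.items())
    }

    diseases: list[AnnotationSet] = []
    for d in range(cfg.n_diseases):
        disease_id = f"DIS:{d:04d}"
        if disease_id in planted:
            gene_idx = planted[disease_id]
            # model index == gene index: model g is gene g's first model
            source = models[gene_idx]
            counterpart = sorted(
                species.partner(c) for c in source.concepts
            )
            n_noise = round(cfg.annotation_noise * len(counterpart))
            keep_idx = rng.choice(
                len(counterpart), size=len(counterpart) - n_noise, replace=False
            )
            kept = {counterpart[i] for i in keep_idx}
            fresh_pool = [c for c in o1_pool if c not in kept]
            noise_idx = rng.choice(len(fresh_pool), size=n_noise, replace=False)
            concepts = kept | {fresh_pool[i] for i in noise_idx}
        else:
            k = int(rng.integers(lo, hi + 1))
            concepts = {
                o1_pool[i] for i in rng.choice(len(o1_pool), size=k, replace=False)
            }
        diseases.append(
            AnnotationSet(owner=disease_id, concepts=frozenset(concepts))
        )
    return models, diseases, orthology, gold


def generate_bundle(cfg: GeneratorConfig) -> Bundle:
    """Generate the full input bundle from one seeded RNG stream."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    entities, qualities = generate_support_ontologies(cfg)
    species = generate_species_pair(cfg, (entities, qualities), rng=rng)
    models, diseases, orthology, gold = generate_annotation_corpus(
        cfg, species, rng=rng
    )
    return Bundle(
        cfg=cfg,
        entities=entities,
        qualities=qualities,
        species=species,
        models=models,
        diseases=diseases,
        orthology=orthology,
        gold=gold,
    )


# ---------------------------------------------------------------------------
# on-disk bundle
# ---------------------------------------------------------------------------

BUNDLE_FILES = (
    "entities.obo",
    "qualities.obo",
    "species1.obo",
    "species1_defs.obo",
    "species2.obo",
    "species2_defs.obo",
    "models.tsv",
    "diseases.tsv",
    "orthology.tsv",
    "gold.tsv",
)


def write_bundle(bundle: Bundle, outdir: str | Path) -> Path:
    """Write every input file plus a manifest with config and checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contents = {
        "entities.obo": obo.write_obo(bundle.entities),
        "qualities.obo": obo.write_obo(bundle.qualities),
        "species1.obo": obo.write_obo(bundle.species.o1),
        "species1_defs.obo": obo.write_eq_definitions(bundle.species.defs1),
        "species2.obo": obo.write_obo(bundle.species.o2),
        "species2_defs.obo": obo.write_eq_definitions(bundle.species.defs2),
        "models.tsv": write_model_annotations(bundle.models),
        "diseases.tsv": write_disease_annotations(bundle.diseases),
        "orthology.tsv": write_orthology(bundle.orthology),
        "gold.tsv": write_gold(bundle.gold),
    }
    checksums = {}
    for name, text in contents.items():
        (outdir / name).write_text(text)
        checksums[name] = hashlib.sha256(text.encode()).hexdigest()
    manifest = {
        "config": dataclasses.asdict(bundle.cfg),
        "checksums": checksums,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
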