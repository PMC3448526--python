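"""Synthetic study generator: determinism, planted structure, coverage."""

import dataclasses

import numpy as np
import pytest

from phenobridge import (
    ConfigError,
    GeneratorConfig,
    eq_subsumes,
    formal_axioms,
    generate_bundle,
    generate_species_pair,
    generate_support_ontologies,
    lexical_seed_pairs,
    normalize_label,
    small_preset,
    write_bundle,
)
from phenobridge.mapping import build_mapping, seeds_to_axioms
from phenobridge.synthetic import BUNDLE_FILES, SPECIES1_PREFIX, SPECIES2_PREFIX


class TestSupportOntologies:
    def test_depth_one_branching_two(self):
        cfg = small_preset(
            entity_depth=1,
            entity_branching=2,
            quality_depth=1,
            quality_branching=2,
            n_concepts_per_species=5,
            annotations_per_entity=(1, 2),
            n_genes=2,
            n_models=2,
            n_diseases=2,
            n_true_associations=1,
        )
        entities, qualities = generate_support_ontologies(cfg)
        assert len(entities) == 3 and len(qualities) == 3

    @pytest.mark.parametrize("depth,branching", [(2, 2), (3, 3), (2, 4)])
    def test_geometric_node_count(self, depth, branching):
        cfg = small_preset(
            entity_depth=depth,
            entity_branching=branching,
            quality_depth=depth,
            quality_branching=branching,
            n_concepts_per_species=5,
            annotations_per_entity=(1, 2),
        )
        entities, _ = generate_support_ontologies(cfg)
        assert len(entities) == (branching ** (depth + 1) - 1) // (branching - 1)

    def test_same_seed_identical(self):
        cfg = small_preset(seed=9)
        a = generate_support_ontologies(cfg)
        b = generate_support_ontologies(cfg)
        for oa, ob in zip(a, b):
            assert set(oa) == set(ob)
            assert all(oa[c].label == ob[c].label for c in oa)


class TestSpeciesPair:
    def test_is_a_follows_eq_subsumption(self):
        cfg = small_preset(seed=2, n_concepts_per_species=60)
        supports = generate_support_ontologies(cfg)
        entities, qualities = supports
        sp = generate_species_pair(cfg, supports)
        root = f"{SPECIES1_PREFIX}:{0:07d}"
        for cid in sp.o1.active_ids():
            if cid == root:
                continue
            for parent in sp.o1[cid].parent_ids:
                if parent == root:
                    continue
                assert eq_subsumes(
                    sp.defs1[cid], sp.defs1[parent], qualities, entities
                )

    def test_full_sharing_recovers_every_partner(self):
        # frac_shared_labels=1 with an identical EQ pool: the lexical matcher
        # must recover each concept's identical-EQ partner (generator
        # bookkeeping vs matcher output)
        cfg = small_preset(seed=3, n_concepts_per_species=50)
        sp = generate_species_pair(cfg, generate_support_ontologies(cfg))
        pairs = {(p.left, p.right) for p in lexical_seed_pairs(sp.o1, sp.o2)}
        for cid in sp.o1.active_ids():
            if cid.endswith(f"{0:07d}"):
                continue
            assert (cid, sp.partner(cid)) in pairs

    def test_no_definitions_no_axioms(self):
        cfg = small_preset(seed=4, frac_defined_1=0.0, n_concepts_per_species=40)
        supports = generate_support_ontologies(cfg)
        entities, qualities = supports
        sp = generate_species_pair(cfg, supports)
        assert sp.defs1 == {}
        assert formal_axioms(sp.defs1, sp.defs2, qualities, entities) == set()

    def test_no_shared_labels_no_seeds(self):
        cfg = small_preset(seed=5, frac_shared_labels=0.0, n_concepts_per_species=40)
        sp = generate_species_pair(cfg, generate_support_ontologies(cfg))
        assert lexical_seed_pairs(sp.o1, sp.o2) == set()

    def test_labels_of_partners_normalize_identically_when_shared(self):
        cfg = small_preset(seed=6, n_concepts_per_species=30)
        sp = generate_species_pair(cfg, generate_support_ontologies(cfg))
        for cid in sp.o1.active_ids():
            if cid.endswith(f"{0:07d}"):
                continue
            partner = sp.partner(cid)
            pool1 = {normalize_label(s) for s in [sp.o1[cid].label] + sp.o1[cid].synonyms}
            pool2 = {normalize_label(s) for s in [sp.o2[partner].label] + sp.o2[partner].synonyms}
            assert pool1 & pool2

    def test_formal_coverage_at_least_defined_fraction(self):
        # the species with the smaller (nested) definition set always maps at
        # least its defined fraction: each defined concept has a defined
        # identical-EQ partner
        cfg = small_preset(
            seed=7,
            n_concepts_per_species=80,
            frac_defined_1=0.4,
            frac_defined_2=0.7,
            frac_shared_labels=0.0,
        )
        supports = generate_support_ontologies(cfg)
        entities, qualities = supports
        sp = generate_species_pair(cfg, supports)
        axioms = formal_axioms(sp.defs1, sp.defs2, qualities, entities)
        m = build_mapping(
            sp.o1, sp.o2, axioms, SPECIES1_PREFIX, SPECIES2_PREFIX, method="formal"
        )
        n_active = len(sp.o1.active_ids())
        assert m.mapped_count() / n_active >= cfg.frac_defined_1 * (
            (n_active - 1) / n_active
        )


class TestAnnotationCorpus:
    def test_planted_disease_mirrors_model_profile(self):
        cfg = small_preset(seed=8)
        bundle = generate_bundle(cfg)
        planted = {d: g for g, d in bundle.gold}
        mouse_of = {h: m for m, h in bundle.orthology.items()}
        models_by_gene = {m.gene: m for m in bundle.models}
        for disease in bundle.diseases:
            human_gene = planted.get(disease.owner)
            if human_gene is None:
                continue
            gene = mouse_of[human_gene]
            counterpart = {
                bundle.species.partner(c)
                for c in models_by_gene[gene].concepts
            }
            # noise=0: the disease profile is exactly the counterpart set
            assert disease.concepts == frozenset(counterpart)

    def test_no_positives_rejected_by_roc(self):
        from phenobridge import EvaluationError, rank_pairs, roc_and_auc

        cfg = small_preset(seed=9, n_true_associations=0)
        bundle = generate_bundle(cfg)
        from phenobridge.pipeline import build_all_mappings

        mappings = build_all_mappings(bundle)
        pairs = rank_pairs(
            bundle.diseases,
            bundle.models,
            mappings[("lexical", "1to2")],
            "disease_to_model_space",
            bundle.orthology,
            bundle.gold,
        )
        with pytest.raises(EvaluationError):
            roc_and_auc(pairs)

    def test_config_errors(self):
        with pytest.raises(ConfigError):
            small_preset(n_true_associations=99).validate()
        with pytest.raises(ConfigError):
            small_preset(annotation_noise=1.5).validate()
        with pytest.raises(ConfigError):
            small_preset(
                entity_depth=1,
                entity_branching=1,
                quality_depth=1,
                quality_branching=1,
            ).validate()

    def test_bundle_bytes_deterministic(self, tmp_path):
        cfg = small_preset(seed=10, n_concepts_per_species=60)
        dir_a = write_bundle(generate_bundle(cfg), tmp_path / "a")
        dir_b = write_bundle(generate_bundle(cfg), tmp_path / "b")
        for name in BUNDLE_FILES + ("manifest.json",):
            assert (dir_a / name).read_bytes() == (dir_b / name).read_bytes()

    def test_auc_degrades_monotonically_with_noise(self):
        # mean lexical AUC over 20 seeds is non-increasing in annotation
        # noise (0.02 slack for sampling error) and near chance at noise=1
        from phenobridge import lexical_seed_pairs, rank_pairs, roc_and_auc
        from phenobridge.mapping import build_mapping, seeds_to_axioms

        tiny = dict(
            n_concepts_per_species=60,
            n_genes=8,
            n_models=8,
            n_diseases=8,
            n_true_associations=5,
            annotations_per_entity=(3, 4),
        )
        means = []
        for noise in (0.0, 0.25, 0.5, 0.75, 1.0):
            aucs = []
            for seed in range(20):
                cfg = small_preset(seed=seed, annotation_noise=noise, **tiny)
                bundle = generate_bundle(cfg)
                seeds = lexical_seed_pairs(bundle.species.o1, bundle.species.o2)
                m = build_mapping(
                    bundle.species.o1,
                    bundle.species.o2,
                    seeds_to_axioms(seeds),
                    SPECIES1_PREFIX,
                    SPECIES2_PREFIX,
                    method="lexical",
                )
                pairs = rank_pairs(
                    bundle.diseases,
                    bundle.models,
                    m,
                    "disease_to_model_space",
                    bundle.orthology,
                    bundle.gold,
                )
                aucs.append(roc_and_auc(pairs).auc)
            means.append(float(np.mean(aucs)))
        for lower_noise, higher_noise in zip(means, means[1:]):
            assert higher_noise <= lower_noise + 0.02
        assert 0.4 <= means[-1] <= 0.6

    def test_different_seed_changes_bundle(self, tmp_path):
        a = write_bundle(generate_bundle(small_preset(seed=1)), tmp_path / "a")
        b = write_bundle(generate_bundle(small_preset(seed=2)), tmp_path / "b")
        assert (a / "models.tsv").read_text() != (b / "models.tsv").read_text()
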