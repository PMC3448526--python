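"""Translation, cosine similarity, ranking and pooled ROC/AUC."""

import math

import numpy as np
import pytest

from phenobridge import (
    AnnotationSet,
    EvaluationError,
    Mapping,
    RankedPair,
    UsageError,
    cosine_similarity,
    rank_pairs,
    roc_and_auc,
    translate,
)


def mann_whitney_auc(pairs):
    """Concordance oracle: fraction of P/N pairs ranked correctly."""
    pos = [p.similarity for p in pairs if p.positive]
    neg = [p.similarity for p in pairs if not p.positive]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else 0.5 if a == b else 0.0
    return total / (len(pos) * len(neg))


def _mapping(entries):
    return Mapping(
        source_prefix="HP",
        target_prefix="MP",
        entries={k: frozenset(v) for k, v in entries.items()},
    )


class TestTranslate:
    def test_all_unmapped_empty(self):
        s = AnnotationSet(owner="DIS:0001", concepts=frozenset({"HP:0000001"}))
        assert translate(s, _mapping({})) == frozenset()

    def test_single_concept(self):
        s = AnnotationSet(owner="DIS:0001", concepts=frozenset({"HP:0000001"}))
        m = _mapping({"HP:0000001": {"MP:0000001", "MP:0000002"}})
        assert translate(s, m) == {"MP:0000001", "MP:0000002"}

    def test_union_without_multiplicity(self):
        s = AnnotationSet(
            owner="DIS:0001",
            concepts=frozenset({"HP:0000001", "HP:0000002"}),
        )
        m = _mapping(
            {
                "HP:0000001": {"MP:0000001", "MP:0000002"},
                "HP:0000002": {"MP:0000002", "MP:0000003"},
            }
        )
        assert translate(s, m) == {"MP:0000001", "MP:0000002", "MP:0000003"}

    def test_prefix_mismatch(self):
        s = AnnotationSet(owner="DIS:0001", concepts=frozenset({"MP:0000001"}))
        with pytest.raises(UsageError):
            translate(s, _mapping({}))

    def test_superset_mapping_never_decreases_overlap(self):
        rng = np.random.default_rng(0)
        universe = [f"MP:{i:07d}" for i in range(20)]
        source = [f"HP:{i:07d}" for i in range(10)]
        small = {
            c: set(rng.choice(universe, size=rng.integers(1, 4), replace=False))
            for c in source
        }
        big = {
            c: v | set(rng.choice(universe, size=2, replace=False))
            for c, v in small.items()
        }
        b = set(rng.choice(universe, size=6, replace=False))
        for k in range(1, 10):
            s = AnnotationSet(owner="X:1", concepts=frozenset(source[:k]))
            inter_small = translate(s, _mapping(small)) & b
            inter_big = translate(s, _mapping(big)) & b
            assert inter_small <= inter_big


class TestCosineSimilarity:
    def test_equal_sets(self):
        assert cosine_similarity({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert cosine_similarity({"a"}, {"b"}) == 0.0

    def test_half_overlap(self):
        # |a∩b|=1, norms sqrt(2)*sqrt(2): direct evaluation gives 0.5
        assert cosine_similarity({"p", "q"}, {"q", "r"}) == pytest.approx(0.5)

    def test_empty_is_zero(self):
        assert cosine_similarity(set(), {"a"}) == 0.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(1)
        items = list("abcdefghij")
        for _ in range(50):
            a = set(rng.choice(items, size=rng.integers(0, 8)))
            b = set(rng.choice(items, size=rng.integers(0, 8)))
            s = cosine_similarity(a, b)
            assert s == cosine_similarity(b, a)
            assert 0.0 <= s <= 1.0
            if a and a == b:
                assert s == 1.0


def _make_models(annotations):
    return [
        AnnotationSet(
            owner=f"MOD:{i:04d}",
            concepts=frozenset(c),
            gene=f"MG:{i:04d}",
        )
        for i, c in enumerate(annotations)
    ]


class TestRankPairs:
    ORTHO = {f"MG:{i:04d}": f"HG:{i:04d}" for i in range(4)}

    def test_single_combination(self):
        diseases = [
            AnnotationSet(owner="DIS:0001", concepts=frozenset({"HP:0000001"}))
        ]
        models = _make_models([{"MP:0000001"}])
        m = _mapping({"HP:0000001": {"MP:0000001"}})
        pairs = rank_pairs(
            diseases, models, m, "disease_to_model_space", self.ORTHO,
            {("HG:0000", "DIS:0001")},
        )
        assert len(pairs) == 1
        assert pairs[0].positive and pairs[0].similarity == 1.0

    def test_sorted_descending_with_deterministic_ties(self):
        diseases = [
            AnnotationSet(owner="DIS:0001", concepts=frozenset({"HP:0000001"})),
            AnnotationSet(owner="DIS:0002", concepts=frozenset({"HP:0000002"})),
        ]
        models = _make_models([{"MP:0000001"}, {"MP:0000001", "MP:0000002"}])
        m = _mapping(
            {"HP:0000001": {"MP:0000001"}, "HP:0000002": {"MP:0000002"}}
        )
        pairs = rank_pairs(
            diseases, models, m, "disease_to_model_space", self.ORTHO, set()
        )
        sims = [p.similarity for p in pairs]
        assert sims == sorted(sims, reverse=True)
        tied = [(p.disease, p.model) for p in pairs if p.similarity == sims[-1]]
        assert tied == sorted(tied)

    def test_missing_ortholog_forces_negative(self):
        diseases = [
            AnnotationSet(owner="DIS:0001", concepts=frozenset({"HP:0000001"}))
        ]
        models = _make_models([{"MP:0000001"}])
        m = _mapping({"HP:0000001": {"MP:0000001"}})
        pairs = rank_pairs(
            diseases, models, m, "disease_to_model_space", {},
            {("HG:0000", "DIS:0001")},
        )
        assert not pairs[0].positive

    def test_empty_translation_scores_zero_and_stays(self):
        diseases = [
            AnnotationSet(owner="DIS:0001", concepts=frozenset({"HP:0000009"}))
        ]
        models = _make_models([{"MP:0000001"}])
        pairs = rank_pairs(
            diseases, models, _mapping({}), "disease_to_model_space",
            self.ORTHO, set(),
        )
        assert len(pairs) == 1 and pairs[0].similarity == 0.0

    def test_unknown_scenario(self):
        with pytest.raises(UsageError):
            rank_pairs([], [], _mapping({}), "sideways", {}, set())


class TestRocAndAuc:
    @staticmethod
    def _pairs(scored):
        return [
            RankedPair(
                disease=f"DIS:{i:04d}",
                model=f"MOD:{i:04d}",
                gene=f"MG:{i:04d}",
                similarity=s,
                positive=p,
            )
            for i, (s, p) in enumerate(scored)
        ]

    def test_perfect_separation(self):
        result = roc_and_auc(
            self._pairs([(0.9, True), (0.8, True), (0.2, False), (0.1, False)])
        )
        assert result.auc == 1.0

    def test_single_tie_block_is_diagonal(self):
        result = roc_and_auc(
            self._pairs([(0.5, True), (0.5, False), (0.5, True), (0.5, False)])
        )
        assert result.auc == pytest.approx(0.5)
        assert result.points[0] == (0.0, 0.0)
        assert result.points[-1] == (1.0, 1.0)

    def test_interleaved_example(self):
        # brute-force concordance: 3 of 4 P/N pairs concordant -> 0.75
        pairs = self._pairs(
            [(0.9, True), (0.8, False), (0.7, True), (0.1, False)]
        )
        result = roc_and_auc(pairs)
        assert result.auc == pytest.approx(0.75)
        assert result.auc == pytest.approx(mann_whitney_auc(pairs))

    def test_requires_both_classes(self):
        with pytest.raises(EvaluationError):
            roc_and_auc(self._pairs([(0.5, True), (0.4, True)]))

    def test_curve_monotone(self):
        rng = np.random.default_rng(2)
        pairs = self._pairs(
            [(float(rng.random()), bool(rng.random() < 0.3)) for _ in range(60)]
        )
        result = roc_and_auc(pairs)
        xs, ys = zip(*result.points)
        assert list(xs) == sorted(xs) and list(ys) == sorted(ys)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        # coarse scores force plenty of ties
        pairs = self._pairs(
            [
                (round(float(rng.random()), 1), bool(rng.random() < 0.25))
                for _ in range(n)
            ]
        )
        if len({p.positive for p in pairs}) < 2:
            pairs = pairs[:-2] + self._pairs([(0.5, True), (0.4, False)])
        assert roc_and_auc(pairs).auc == pytest.approx(mann_whitney_auc(pairs))

    def test_label_shuffle_centers_on_half(self):
        rng = np.random.default_rng(3)
        base = self._pairs(
            [(float(rng.random()), i < 20) for i in range(100)]
        )
        aucs = []
        labels = [p.positive for p in base]
        for _ in range(200):
            rng.shuffle(labels)
            shuffled = [
                RankedPair(p.disease, p.model, p.gene, p.similarity, l)
                for p, l in zip(base, labels)
            ]
            aucs.append(roc_and_auc(shuffled).auc)
        mean = float(np.mean(aucs))
        se = float(np.std(aucs, ddof=1)) / math.sqrt(len(aucs))
        assert abs(mean - 0.5) <= 3 * se
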