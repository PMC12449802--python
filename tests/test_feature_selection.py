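import numpy as np
import pytest

import magselect as m
from magselect.feature_selection import CVParams
from sklearn.model_selection import StratifiedKFold


def auroc_oracle(scores, labels):
    """Brute-force Mann-Whitney pair count with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _noise_matrix(n_genomes, n_samples, seed):
    rng = np.random.default_rng(seed)
    return m.AbundanceMatrix(
        [f"g{i:03d}" for i in range(n_genomes)],
        [f"s{j:03d}" for j in range(n_samples)],
        rng.gamma(2.0, 1.0, size=(n_genomes, n_samples)),
    )


class TestAuroc:
    def test_perfect_ranking(self):
        assert m.auroc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert m.auroc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5

    def test_hand_pair_count(self):
        # positives 0.2, 0.8 vs negatives 0.6, 0.4: 2 of 4 pairs correct
        scores, labels = [0.2, 0.8, 0.6, 0.4], [1, 1, 0, 0]
        assert auroc_oracle(scores, labels) == 0.5
        assert m.auroc(scores, labels) == 0.5

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            m.auroc([0.1, 0.2], [1, 1])

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            n = int(rng.integers(4, 25))
            labels = np.zeros(n, int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.uniform(0, 1, n), int(rng.integers(1, 4)))
            assert m.auroc(scores, labels) == pytest.approx(
                auroc_oracle(scores, labels), abs=1e-12
            )


class TestImportanceScores:
    def test_planted_feature_ranks_first(self):
        matrix = _noise_matrix(51, 40, seed=3)
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        values = matrix.values.copy()
        values[25] = np.r_[np.full(20, 10.0), np.full(20, 0.5)]  # separator
        matrix = m.AbundanceMatrix(matrix.genome_ids, matrix.sample_ids, values)
        ranking = m.importance_scores(matrix, labels, n_trees=200, n_repeats=5, seed=1)
        assert ranking[0][0] == "g025"
        assert ranking[0][1] > 0

    def test_null_importances_centered_on_zero(self):
        matrix = _noise_matrix(30, 40, seed=5)
        rng = np.random.default_rng(6)
        labels = rng.permutation(np.r_[np.ones(20, int), np.zeros(20, int)])
        ranking = m.importance_scores(matrix, labels, n_trees=200, n_repeats=5, seed=2)
        scores = np.array([s for _, s in ranking])
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 2 * se + 1e-9

    def test_seeded_determinism_and_permutation_of_input(self):
        matrix = _noise_matrix(20, 30, seed=7)
        labels = np.r_[np.ones(15, int), np.zeros(15, int)]
        r1 = m.importance_scores(matrix, labels, n_trees=100, n_repeats=3, seed=9)
        r2 = m.importance_scores(matrix, labels, n_trees=100, n_repeats=3, seed=9)
        assert r1 == r2
        assert sorted(g for g, _ in r1) == matrix.genome_ids

    def test_single_class_is_error(self):
        matrix = _noise_matrix(5, 10, seed=1)
        with pytest.raises(ValueError):
            m.importance_scores(matrix, np.ones(10, int))

    def test_impurity_mode(self):
        matrix = _noise_matrix(10, 20, seed=2)
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        r = m.importance_scores(matrix, labels, n_trees=50, seed=3, mode="impurity")
        assert sorted(g for g, _ in r) == matrix.genome_ids
        assert all(s >= 0 for _, s in r)


class TestRepeatedCvAuroc:
    def test_separable_subset_reaches_one(self):
        matrix = _noise_matrix(3, 40, seed=4)
        values = matrix.values.copy()
        values[0] = np.r_[np.full(20, 10.0), np.full(20, 0.1)]
        matrix = m.AbundanceMatrix(matrix.genome_ids, matrix.sample_ids, values)
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        mean_a, per_repeat = m.repeated_cv_auroc(matrix, labels,
                                                 CVParams(n_trees=50, seed=1))
        assert mean_a == 1.0 and per_repeat == [1.0, 1.0, 1.0]

    def test_pure_noise_near_chance(self):
        # at 200 samples the per-dataset null AUROC concentrates near 0.5
        matrix = _noise_matrix(10, 200, seed=8)
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        mean_a, _ = m.repeated_cv_auroc(
            matrix, labels, CVParams(repeats=20, n_trees=50, seed=2)
        )
        assert 0.35 <= mean_a <= 0.65

    def test_seeded_determinism(self):
        matrix = _noise_matrix(5, 30, seed=9)
        labels = np.r_[np.ones(15, int), np.zeros(15, int)]
        p = CVParams(n_trees=50, seed=5)
        assert m.repeated_cv_auroc(matrix, labels, p) == \
            m.repeated_cv_auroc(matrix, labels, p)

    def test_k_lowered_to_minority(self):
        matrix = _noise_matrix(4, 13, seed=10)
        labels = np.r_[np.ones(3, int), np.zeros(10, int)]
        mean_a, reps = m.repeated_cv_auroc(matrix, labels, CVParams(k=10, n_trees=20, seed=1))
        assert len(reps) == 3 and 0 <= mean_a <= 1

    def test_minority_below_two_is_error(self):
        matrix = _noise_matrix(4, 11, seed=11)
        labels = np.r_[np.ones(1, int), np.zeros(10, int)]
        with pytest.raises(ValueError):
            m.repeated_cv_auroc(matrix, labels, CVParams(n_trees=20, seed=1))


def test_stratification_balance():
    """Every fold's class ratio deviates from global by <= 1 sample per class."""
    labels = np.r_[np.ones(23, int), np.zeros(37, int)]
    for r in range(3):
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=r)
        for _, test in skf.split(np.zeros((60, 1)), labels):
            n_pos = labels[test].sum()
            n_neg = len(test) - n_pos
            assert abs(n_pos - 2.3) <= 1
            assert abs(n_neg - 3.7) <= 1


class TestCumulativeSelection:
    def test_degenerate_single_genome(self):
        matrix = _noise_matrix(1, 20, seed=12)
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        ranking = m.importance_scores(matrix, labels, n_trees=20, n_repeats=2, seed=1)
        res = m.cumulative_selection(matrix, labels, ranking,
                                     cv_params=CVParams(n_trees=20, seed=1))
        assert len(res.curve) == 1 and res.best_size == 1

    def test_curve_invariants(self, small_cohort):
        _, matrix, metadata, _, _ = small_cohort
        from tests.conftest import labels_for

        labels = labels_for(matrix, metadata)
        sub = matrix.subset_genomes(matrix.genome_ids[:12])
        ranking = m.importance_scores(sub, labels, n_trees=100, n_repeats=3, seed=2)
        res = m.cumulative_selection(sub, labels, ranking, cap=8,
                                     cv_params=CVParams(n_trees=50, seed=3))
        assert [s for s, _ in res.curve] == list(range(1, 9))
        assert all(0 <= a <= 1 for _, a in res.curve)
        assert res.best_auroc == max(a for _, a in res.curve)
        assert res.best_size == min(s for s, a in res.curve if a == res.best_auroc)
        assert res.best_subset == [g for g, _ in ranking[: res.best_size]]

    def test_ranking_must_cover_matrix(self):
        matrix = _noise_matrix(3, 10, seed=13)
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        with pytest.raises(ValueError):
            m.cumulative_selection(matrix, labels, [("g000", 1.0)],
                                   cv_params=CVParams(n_trees=10, seed=1))


class TestAblation:
    def test_identity_ablation_reproduces_best(self):
        matrix = _noise_matrix(6, 24, seed=14)
        labels = np.r_[np.ones(12, int), np.zeros(12, int)]
        ranking = m.importance_scores(matrix, labels, n_trees=50, n_repeats=2, seed=4)
        cv = CVParams(n_trees=50, seed=4)
        res = m.cumulative_selection(matrix, labels, ranking, cv_params=cv)
        same = m.ablation_auroc(matrix, labels, res.best_subset, set(), cv)
        assert same == res.best_auroc

    def test_empty_remainder_is_error(self):
        matrix = _noise_matrix(2, 10, seed=15)
        labels = np.r_[np.ones(5, int), np.zeros(5, int)]
        with pytest.raises(ValueError):
            m.ablation_auroc(matrix, labels, ["g000"], {"g000"},
                             CVParams(n_trees=10, seed=1))
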