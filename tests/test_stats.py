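import numpy as np
import pytest
from scipy import stats as sps

from nodulemap import stats


# ------------------------------------------------------------------ #
# independent oracles


def brute_force_auc(labels, scores):
    """Exhaustive pairwise concordance with half credit for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def delong_loop_oracle(labels, scores_a, scores_b):
    """DeLong structural-components covariance computed with explicit loops."""
    labels = np.asarray(labels)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    m, n = len(pos_idx), len(neg_idx)

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    aucs, v10s, v01s = [], [], []
    for scores in (scores_a, scores_b):
        x = scores[pos_idx]
        y = scores[neg_idx]
        v10 = np.array([np.mean([psi(xj, yi) for yi in y]) for xj in x])
        v01 = np.array([np.mean([psi(xj, yi) for xj in x]) for yi in y])
        aucs.append(v10.mean())
        v10s.append(v10)
        v01s.append(v01)
    s10 = np.cov(np.asarray(v10s), ddof=1)
    s01 = np.cov(np.asarray(v01s), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        return 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var)
    return 2.0 * sps.norm.sf(abs(z))


# ------------------------------------------------------------------ #
# roc_auc


class TestRocAuc:
    def test_perfect_separation(self):
        res = stats.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert res.auc == 1.0

    def test_all_ties(self):
        res = stats.roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert res.auc == pytest.approx(0.5)

    def test_three_of_four_concordant(self):
        # 3 of 4 (pos, neg) pairs concordant -> 0.75
        res = stats.roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert res.auc == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(stats.UndefinedAUCError):
            stats.roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_curve_monotone(self, rng):
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.random(60)
        res = stats.roc_auc(labels, scores)
        assert np.all(np.diff(res.fpr) >= 0)
        assert np.all(np.diff(res.tpr) >= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = rng.choice(np.linspace(0, 1, 11), n)  # force some ties
        res = stats.roc_auc(labels, scores)
        assert res.auc == pytest.approx(brute_force_auc(labels, scores), abs=1e-12)


# ------------------------------------------------------------------ #
# DeLong


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        labels = np.array([0, 0, 1, 1, 0, 1])
        scores = np.array([0.1, 0.2, 0.7, 0.9, 0.3, 0.6])
        a = stats.roc_auc(labels, scores)
        b = stats.roc_auc(labels, scores.copy())
        res = stats.delong_test(a, b)
        assert res.p_value == 1.0
        assert res.degenerate

    def test_small_paired_toy_matches_loop_oracle(self):
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        sa = np.array([0.9, 0.8, 0.6, 0.55, 0.5, 0.4, 0.3, 0.2])
        sb = np.array([0.7, 0.9, 0.4, 0.8, 0.6, 0.3, 0.5, 0.1])
        p = stats.delong_test(
            stats.roc_auc(labels, sa), stats.roc_auc(labels, sb)
        ).p_value
        assert p == pytest.approx(delong_loop_oracle(labels, sa, sb), abs=1e-12)

    def test_large_auc_gap_significant(self, rng):
        n = 200
        labels = np.r_[np.ones(n), np.zeros(n)]
        # classifier A: AUC ~ 0.95; classifier B: ~ 0.55
        sa = np.r_[rng.normal(2.3, 1, n), rng.normal(0, 1, n)]
        sb = np.r_[rng.normal(0.18, 1, n), rng.normal(0, 1, n)]
        res = stats.delong_test(stats.roc_auc(labels, sa), stats.roc_auc(labels, sb))
        assert res.p_value < 0.001

    def test_unpaired_labels_rejected(self):
        a = stats.roc_auc([0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8])
        b = stats.roc_auc([1, 0, 0, 1], [0.1, 0.9, 0.2, 0.8])
        with pytest.raises(ValueError):
            stats.delong_test(a, b)


class TestPvalueMatrix:
    def test_identical_rocs_off_diagonal_one(self):
        labels = np.array([0, 1, 0, 1, 0, 1])
        scores = np.array([0.2, 0.8, 0.1, 0.7, 0.4, 0.9])
        rocs = [stats.roc_auc(labels, scores) for _ in range(3)]
        mat = stats.pvalue_matrix(rocs)
        assert np.allclose(mat.p_values, 1.0)

    def test_symmetric_with_unit_diagonal(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        rocs = [stats.roc_auc(labels, rng.random(40)) for _ in range(4)]
        mat = stats.pvalue_matrix(rocs)
        assert np.array_equal(mat.p_values, mat.p_values.T)
        assert np.all(np.diag(mat.p_values) == 1.0)
        assert np.all((mat.p_values >= 0) & (mat.p_values <= 1))

    def test_display_floor(self):
        mat = stats.ComparisonMatrix(p_values=np.array([[1.0, 1e-20], [1e-20, 1.0]]))
        assert mat.display[0, 1] == 1e-14
        assert mat.p_values[0, 1] == 1e-20  # raw value retained


# ------------------------------------------------------------------ #
# partitioning / averaging / t-tests / dice


class TestPartitionDataset:
    def test_canonical_2602_split(self):
        split = stats.partition_dataset(2602, k=5, seed=0)
        assert split.sizes.tolist() == [520, 520, 520, 520, 522]

    def test_n_equals_k(self):
        split = stats.partition_dataset(5, k=5, seed=1)
        assert split.sizes.tolist() == [1, 1, 1, 1, 1]

    def test_remainder_rule_n12(self):
        split = stats.partition_dataset(12, k=5, seed=2)
        assert split.sizes.tolist() == [2, 2, 2, 2, 4]

    def test_disjoint_exhaustive(self):
        split = stats.partition_dataset(101, k=5, seed=3)
        seen = np.concatenate([split.indices(s) for s in range(5)])
        assert sorted(seen) == list(range(101))

    def test_too_few_items(self):
        with pytest.raises(ValueError):
            stats.partition_dataset(3, k=5)


class TestRepetitionAverage:
    def test_identical_columns(self):
        table = np.tile([[0.3], [0.7]], (1, 5))
        assert np.allclose(stats.repetition_average(table), [0.3, 0.7])

    def test_arithmetic_mean(self):
        assert stats.repetition_average([[0.2, 0.4, 0.6, 0.8, 1.0]])[0] == pytest.approx(0.6)

    def test_missing_repetition_errors(self):
        with pytest.raises(ValueError):
            stats.repetition_average([[0.1, np.nan]])


class TestPairedTtest:
    def test_identical_columns_degenerate(self):
        table = np.tile([[0.9], [0.91], [0.92]], (1, 2))
        res = stats.paired_ttest_regions(table)
        assert res["p_values"][0, 1] == 1.0
        assert res["degenerate"][0, 1]

    def test_hand_computed_t(self):
        a = [0.90, 0.91, 0.89, 0.92, 0.90]
        b = [0.70, 0.72, 0.69, 0.71, 0.70]
        res = stats.paired_ttest_regions(np.column_stack([a, b]))
        # diffs [.20,.19,.20,.21,.20]: t = 0.2 / (0.0070711/sqrt(5)) ~ 63.2
        t_hand = 0.2 / (np.std(np.subtract(a, b), ddof=1) / np.sqrt(5))
        p_hand = 2 * sps.t.sf(abs(t_hand), df=4)
        assert res["p_values"][0, 1] == pytest.approx(p_hand, rel=1e-9)
        assert res["p_values"][0, 1] < 0.01

    def test_diagonal_is_one(self):
        table = np.random.default_rng(0).random((5, 3))
        res = stats.paired_ttest_regions(table)
        assert np.all(np.diag(res["p_values"]) == 1.0)

    def test_single_subset_rejected(self):
        with pytest.raises(ValueError):
            stats.paired_ttest_regions(np.array([[0.9, 0.8]]))


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((5, 5), bool)
        m[1:3, 1:3] = True
        assert stats.dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert stats.dice(a, b) == 0.0

    def test_arithmetic_case(self):
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:4] = True  # |A| = 4
        b[1:7] = True  # |B| = 6, |A&B| = 3
        assert stats.dice(a, b) == pytest.approx(0.6)

    def test_both_empty_defined_as_one(self):
        assert stats.dice(np.zeros(3, bool), np.zeros(3, bool)) == 1.0

    def test_symmetry(self, rng):
        a = rng.random((8, 8)) > 0.5
        b = rng.random((8, 8)) > 0.5
        assert stats.dice(a, b) == stats.dice(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            stats.dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))
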