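"""Validation-metric tests against independent oracles.

Oracles: a pair-counting ARI built from the n(n-1)/2 point pairs, an
exhaustive permutation average for the expected mutual information, plain
summation re-implementations of entropy/MI/conditional entropy, and
scikit-learn's metrics as an external cross-check.
"""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn import metrics as skm

from stableclust.metrics import (
    ContingencyTable,
    ami,
    ari,
    completeness,
    contingency,
    entropy,
    evaluate_clustering,
    expected_mi,
    homogeneity,
    mutual_information,
    v_measure,
)

# ---------------------------------------------------------------- oracles


def pair_counting_ari(x, y):
    """ARI from explicit point-pair agreement counts."""
    n = len(x)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(range(n), 2):
        same_x, same_y = x[i] == x[j], y[i] == y[j]
        n11 += same_x and same_y
        n00 += (not same_x) and (not same_y)
        n10 += same_x and not same_y
        n01 += (not same_x) and same_y
    num = 2 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    return 1.0 if den == 0 else num / den


def plain_entropy(labels):
    n = len(labels)
    return -sum((c / n) * math.log(c / n) for c in Counter(labels).values())


def plain_mi(x, y):
    n = len(x)
    joint = Counter(zip(x, y))
    px, py = Counter(x), Counter(y)
    return sum((nij / n) * math.log(nij * n / (px[a] * py[b]))
               for (a, b), nij in joint.items())


def permutation_emi(x, y):
    """Exact E{MI} by averaging MI over all arrangements of y's labels."""
    vals = [plain_mi(x, perm) for perm in
            set(itertools.permutations(y))]
    # uniform over distinct arrangements == uniform over permutations,
    # since every distinct arrangement arises from the same number of perms
    return float(np.mean(vals))


def plain_ami(x, y):
    t = contingency(x, y)
    hx, hy = plain_entropy(x), plain_entropy(y)
    e = expected_mi(t)
    return (plain_mi(x, y) - e) / (max(hx, hy) - e)


def random_pair(rng, n=30, kx=3, ky=4):
    return rng.integers(0, kx, size=n), rng.integers(0, ky, size=n)


# ---------------------------------------------------------------- tests


class TestContingency:
    def test_identical_partitions_are_diagonal(self):
        t = contingency([1, 1, 2, 2], [1, 1, 2, 2])
        np.testing.assert_array_equal(t.counts, [[2, 0], [0, 2]])

    def test_crossed_design_is_all_ones(self):
        t = contingency([1, 1, 2, 2], [1, 2, 1, 2])
        np.testing.assert_array_equal(t.counts, np.ones((2, 2)))

    def test_matches_per_point_tally(self, rng):
        x, y = random_pair(rng, n=50)
        t = contingency(x, y)
        xs, ys = np.unique(x), np.unique(y)
        for i, xi in enumerate(xs):
            for j, yj in enumerate(ys):
                assert t.counts[i, j] == int(np.sum((x == xi) & (y == yj)))
        assert t.n == 50
        np.testing.assert_array_equal(t.row_sums, t.counts.sum(axis=1))

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="length"):
            contingency([1, 2], [1, 2, 3])


class TestARI:
    def test_identical_partitions_give_one(self):
        assert ari(contingency([1, 1, 2, 2, 3], [1, 1, 2, 2, 3])) == 1.0

    def test_crossed_design_gives_minus_half(self):
        x, y = [1, 1, 2, 2], [1, 2, 1, 2]
        assert ari(contingency(x, y)) == pytest.approx(-0.5)
        assert pair_counting_ari(x, y) == pytest.approx(-0.5)

    def test_random_partitions_average_near_zero(self, rng):
        fixed = rng.integers(0, 3, size=60)
        vals = [ari(contingency(fixed, rng.integers(0, 3, size=60)))
                for _ in range(200)]
        assert abs(np.mean(vals)) < 0.02

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_oracle_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_pair(rng, n=40)
        value = ari(contingency(x, y))
        assert value == pytest.approx(pair_counting_ari(x, y), abs=1e-9)
        assert value == pytest.approx(skm.adjusted_rand_score(x, y), abs=1e-9)

    def test_degenerate_trivial_partitions(self):
        assert ari(contingency([1, 1, 1], [2, 2, 2])) == 1.0
        assert ari(contingency([1, 2, 3], [4, 5, 6])) == 1.0


class TestEntropy:
    def test_single_cluster_zero(self):
        assert entropy([1] * 25) == 0.0

    def test_two_equal_clusters_log2(self):
        assert entropy([0, 0, 1, 1]) == pytest.approx(math.log(2))
        assert entropy([0, 0, 1, 1], base=2) == pytest.approx(1.0)

    @settings(derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 5), min_size=1, max_size=50))
    def test_non_negative_and_matches_plain_sum(self, labels):
        h = entropy(labels)
        assert h >= 0.0
        assert h == pytest.approx(plain_entropy(labels), abs=1e-12)


class TestMutualInformation:
    def test_independent_crossed_partitions_zero(self):
        assert mutual_information(contingency([1, 1, 2, 2], [1, 2, 1, 2])) == \
            pytest.approx(0.0, abs=1e-12)

    def test_identical_partitions_attain_entropy(self):
        labels = [0, 0, 1, 1, 2]
        assert mutual_information(contingency(labels, labels)) == \
            pytest.approx(entropy(labels), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_pair(rng)
        mi = mutual_information(contingency(x, y))
        assert mi == pytest.approx(plain_mi(x.tolist(), y.tolist()), abs=1e-12)
        assert mi <= min(entropy(x), entropy(y)) + 1e-9


class TestExpectedMI:
    def test_single_cluster_table_zero(self):
        assert expected_mi(ContingencyTable(counts=np.array([[7]]))) == 0.0

    @pytest.mark.parametrize("x, y", [
        ([0, 0, 1, 1], [0, 1, 0, 1]),           # margins (2,2) x (2,2)
        ([0, 0, 0, 1, 1], [0, 0, 1, 1, 1]),
        ([0, 0, 1, 1, 2, 2], [0, 1, 1, 0, 2, 2]),
        ([0, 0, 0, 0, 1, 1, 1, 2], [0, 1, 2, 0, 1, 2, 1, 0]),  # n = 8
    ])
    def test_matches_exhaustive_permutation_average(self, x, y):
        assert expected_mi(contingency(x, y)) == \
            pytest.approx(permutation_emi(tuple(x), tuple(y)), abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_by_entropies(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_pair(rng, n=25)
        e = expected_mi(contingency(x, y))
        assert -1e-9 <= e <= min(entropy(x), entropy(y)) + 1e-9


class TestAMI:
    def test_identical_partitions_give_one(self):
        labels = [0, 0, 1, 1, 2, 2]
        assert ami(labels, labels) == pytest.approx(1.0)

    def test_crossed_design_nonpositive(self):
        assert ami([1, 1, 2, 2], [1, 2, 1, 2]) <= 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_reimplementation_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_pair(rng)
        value = ami(x, y)
        assert value == pytest.approx(plain_ami(x.tolist(), y.tolist()),
                                      abs=1e-9)
        assert value == pytest.approx(
            skm.adjusted_mutual_info_score(x, y, average_method="max"),
            abs=1e-9)
        assert value <= 1.0 + 1e-12

    def test_identical_trivial_partitions_give_one(self):
        assert ami([1, 1, 1], [2, 2, 2]) == 1.0


class TestVMeasureFamily:
    def test_pure_clusters_are_homogeneous(self):
        # every cluster contains a single class
        classes, clusters = ["a", "a", "b", "b"], [1, 1, 2, 3]
        assert homogeneity(classes, clusters) == 1.0
        expected_c = 1 - plain_conditional(clusters, classes) / plain_entropy(clusters)
        assert completeness(classes, clusters) == pytest.approx(expected_c)

    def test_single_cluster_is_complete_not_homogeneous(self):
        classes, clusters = ["a", "a", "b", "b"], [1, 1, 1, 1]
        assert completeness(classes, clusters) == 1.0
        assert homogeneity(classes, clusters) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_pair(rng)
        h, c, v = skm.homogeneity_completeness_v_measure(x, y)
        assert homogeneity(x, y) == pytest.approx(h, abs=1e-9)
        assert completeness(x, y) == pytest.approx(c, abs=1e-9)
        assert v_measure(x, y) == pytest.approx(v, abs=1e-9)
        assert 0.0 <= v_measure(x, y) <= 1.0

    def test_beta_weighting_formula(self):
        # direct harmonic-mean checks with pinned h and c
        assert _v_from(1.0, 1.0) == pytest.approx(1.0)
        assert _v_from(1.0, 0.0) == 0.0
        assert _v_from(0.5, 1.0) == pytest.approx(2 / 3)

    def test_beta_must_be_positive(self):
        with pytest.raises(ValueError, match="beta"):
            v_measure([0, 1], [0, 1], beta=0.0)


def _v_from(h, c, beta=1.0):
    return 0.0 if h + c == 0 else (1 + beta) * h * c / (beta * h + c)


def plain_conditional(rows, cols):
    """H(rows | cols) by direct summation."""
    n = len(rows)
    joint = Counter(zip(rows, cols))
    pc = Counter(cols)
    return -sum((nij / n) * math.log(nij / pc[b])
                for (a, b), nij in joint.items())


class TestInvariances:
    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.lists(st.integers(0, 3), min_size=4, max_size=25),
           st.permutations(list(range(4))))
    def test_relabeling_and_symmetry(self, x, perm):
        rng = np.random.default_rng(len(x))
        y = rng.integers(0, 3, size=len(x)).tolist()
        x2 = [perm[v] for v in x]  # relabeled copy of x
        tx, tx2 = contingency(x, y), contingency(x2, y)
        assert ari(tx) == pytest.approx(ari(tx2), abs=1e-12)
        assert ami(x, y) == pytest.approx(ami(x2, y), abs=1e-9)
        assert v_measure(x, y) == pytest.approx(v_measure(x2, y), abs=1e-12)
        # symmetry in the two arguments (beta = 1 for V)
        assert ari(contingency(x, y)) == pytest.approx(
            ari(contingency(y, x)), abs=1e-12)
        assert ami(x, y) == pytest.approx(ami(y, x), abs=1e-9)
        assert v_measure(x, y) == pytest.approx(v_measure(y, x), abs=1e-12)


def test_evaluate_clustering_bundle():
    out = evaluate_clustering([0, 0, 1, 1], [1, 1, 0, 0])
    assert out["ari"] == 1.0 and out["ami"] == pytest.approx(1.0)
    assert out["k_truth"] == out["k_pred"] == 2
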