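"""KS permutation testing, FDR control, Relief, average hyper-edges."""

import itertools

import numpy as np
import pytest
from scipy.stats import ks_2samp

from hyperbrain.construction import HyperEdge
from hyperbrain.stats import (
    FeatureTable,
    average_hyperedge,
    bh_fdr,
    ks_statistic,
    permutation_test,
    permutation_test_table,
    relief_weights,
    select_features,
)


def _table(values, labels, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{j}" for j in range(values.shape[1])]
    return FeatureTable(values, names, np.asarray(labels))


class TestKS:
    def test_identical_samples_zero(self):
        assert ks_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_disjoint_supports_one(self):
        assert ks_statistic([0.0, 0.0], [1.0, 1.0]) == 1.0

    def test_interleaved_half(self):
        assert ks_statistic([1.0, 2.0], [1.5, 2.5]) == pytest.approx(0.5)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1.0])

    def test_vectorized_null_matches_scipy_with_ties(self):
        # the permutation engine's CDF-difference computation must agree
        # with the reference two-sample statistic, including tied values
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 5, size=20).astype(float)  # heavy ties
            labels = np.array(["a"] * 8 + ["b"] * 12)
            perm = rng.permutation(20)
            got = _single_perm_ks(x, labels == "a")
            want = ks_2samp(x[labels == "a"], x[labels == "b"]).statistic
            assert got == pytest.approx(want)
            x, labels = x[perm], labels[perm]


def _single_perm_ks(x, is_a):
    from hyperbrain.stats import _ks_from_sorted

    order = np.argsort(x, kind="stable")
    xs = x[order]
    dup = np.zeros(len(x), dtype=bool)
    dup[:-1] = xs[:-1] == xs[1:]
    return _ks_from_sorted(is_a[order][None, :], dup, is_a.sum(), (~is_a).sum())[0]


class TestPermutation:
    def test_constant_feature_p_is_one(self):
        labels = np.array(["control"] * 5 + ["patient"] * 5)
        p = permutation_test(np.ones(10), labels, n_perm=200, seed=0)
        assert p == 1.0

    def test_separated_groups_minimal_p(self):
        # 4 + 4 subjects, perfectly separated: only label permutations
        # reproducing the split reach KS = 1
        feature = np.array([0.0] * 4 + [1.0] * 4)
        labels = np.array(["control"] * 4 + ["patient"] * 4)
        n_perm = 999
        p = permutation_test(feature, labels, n_perm=n_perm, seed=1)
        # chance a random permutation separates perfectly = 2/C(8,4) = 1/35
        expected_rate = 2.0 / 70.0
        assert p <= (1 + 3 * expected_rate * n_perm) / (1 + n_perm)
        assert p >= 1.0 / (1 + n_perm)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        feature = rng.standard_normal(20)
        labels = np.array(["control"] * 10 + ["patient"] * 10)
        a = permutation_test(feature, labels, n_perm=300, seed=7)
        b = permutation_test(feature, labels, n_perm=300, seed=7)
        assert a == b

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            permutation_test(np.arange(6.0), np.array(["a"] * 6), n_perm=100, seed=0)

    def test_null_pvalues_approximately_uniform(self):
        # labels carry no signal: pooled p-values across features must be
        # close to uniform
        # unequal group sizes give the KS statistic a fine value lattice;
        # equal sizes would make it too discrete to look uniform.  Each
        # feature gets its own permutation stream so the pooled p-values
        # are independent draws.
        rng = np.random.default_rng(3)
        labels = np.array(["control"] * 14 + ["patient"] * 19)
        pvals = [
            permutation_test(rng.standard_normal(33), labels, n_perm=300, seed=j)
            for j in range(200)
        ]
        pvals = np.array(pvals)
        grid = np.linspace(0, 1, 101)
        ecdf = np.array([(pvals <= g).mean() for g in grid])
        assert np.max(np.abs(ecdf - grid)) < 0.1


class TestFDR:
    def test_step_up_hand_example(self):
        rejected = bh_fdr(np.array([0.01, 0.02, 0.04, 0.5]), q=0.05)
        np.testing.assert_array_equal(rejected, [True, True, False, False])

    def test_all_ones_reject_none(self):
        assert not bh_fdr(np.ones(5), q=0.05).any()

    def test_single_pvalue_reduces_to_threshold(self):
        assert bh_fdr(np.array([0.01]), q=0.05)[0]
        assert not bh_fdr(np.array([0.06]), q=0.05)[0]

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]), q=0.05)


class TestRelief:
    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(0)
        values = np.column_stack([np.ones(10), rng.standard_normal(10)])
        labels = np.array(["control"] * 5 + ["patient"] * 5)
        w = relief_weights(_table(values, labels), seed=0)
        assert w[0] == 0.0

    def test_separating_feature_gets_max_weight(self):
        rng = np.random.default_rng(1)
        n = 20
        labels = np.array(["control"] * 10 + ["patient"] * 10)
        sep = np.r_[np.zeros(10), np.ones(10)]
        values = np.column_stack([sep, rng.standard_normal((n, 4))])
        table = _table(values, labels)
        w = relief_weights(table, seed=3)
        assert np.argmax(w) == 0
        ref = _reference_relief(values, labels)
        np.testing.assert_allclose(np.sort(w), np.sort(ref), atol=1e-12)

    def test_noise_feature_weight_near_zero(self):
        rng = np.random.default_rng(2)
        acc = []
        labels = np.array(["control"] * 8 + ["patient"] * 8)
        for rep in range(50):
            values = rng.standard_normal((16, 3))
            w = relief_weights(_table(values, labels), seed=rep)
            acc.append(w[0])
        assert abs(np.mean(acc)) < 0.05

    def test_single_subject_class_rejected(self):
        values = np.random.default_rng(0).standard_normal((4, 2))
        labels = np.array(["control", "control", "control", "patient"])
        with pytest.raises(ValueError, match="single subject"):
            relief_weights(_table(values, labels))


def _reference_relief(x, y):
    # independent literal reimplementation: every instance once
    n, p = x.shape
    w = np.zeros(p)
    for i in range(n):
        d = np.sqrt(((x - x[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        hits = np.where(y == y[i], d, np.inf)
        misses = np.where(y != y[i], d, np.inf)
        w += np.abs(x[i] - x[misses.argmin()]) - np.abs(x[i] - x[hits.argmin()])
    return w / n


class TestSelectFeatures:
    def test_strong_feature_selected(self):
        rng = np.random.default_rng(4)
        labels = np.array(["control"] * 12 + ["patient"] * 12)
        signal = np.r_[rng.standard_normal(12), rng.standard_normal(12) + 4.0]
        values = np.column_stack([signal, rng.standard_normal((24, 5))])
        res = select_features(_table(values, labels), q=0.05, n_perm=500, seed=0)
        assert res.rejected[0]
        assert res.ks[0] > 0.8


class TestAverageHyperedge:
    def test_identical_edges_pass_through(self):
        edges = [frozenset({0, 3, 5})] * 4
        assert average_hyperedge(edges) == frozenset({0, 3, 5})

    def test_hand_count_with_tie_break(self):
        # degrees 2 and 4 -> d = ceil(3) = 3; counts m:2, a:2, b:1, c:1
        # b beats c on the lower-index tie-break
        edges = [frozenset({0, 1}), frozenset({0, 1, 2, 3})]
        assert average_hyperedge(edges) == frozenset({0, 1, 2})

    def test_accepts_hyperedge_objects(self):
        edges = [
            HyperEdge(centroid=0, members=frozenset({1}), method="lasso", lambda_fraction=0.3),
            HyperEdge(centroid=0, members=frozenset({1, 2}), method="lasso", lambda_fraction=0.3),
        ]
        got = average_hyperedge(edges)
        assert 0 in got and 1 in got

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            edges = [
                frozenset(map(int, rng.choice(8, size=rng.integers(1, 6), replace=False)))
                for _ in range(6)
            ]
            got = average_hyperedge(edges)
            d = int(np.ceil(np.mean([len(e) for e in edges])))
            counts = {v: sum(v in e for e in edges) for e in edges for v in e}
            ranked = sorted(counts, key=lambda v: (-counts[v], v))
            assert got == frozenset(ranked[:d])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            average_hyperedge([])
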