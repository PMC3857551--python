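import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import squareform

from coactnet.cluster_select import (
    ccc_of_metadata,
    class_distances,
    cophenetic_cc,
    cophenetic_distances,
    correlation_distances,
    scan_model_orders,
    single_linkage,
)
from coactnet.metaproject import MetadataMatrix
from oracles import brute_ccc, brute_cophenetic, brute_pearson, brute_single_linkage, random_ultrametric


def meta(values):
    values = np.asarray(values, dtype=float)
    return MetadataMatrix(values=values, class_names=[f"c{i}" for i in range(len(values))],
                          d=values.shape[1])


class TestClassDistances:
    def test_identical_rows_distance_zero(self):
        d = class_distances(meta([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_antiproportional_rows_distance_two(self):
        d = class_distances(meta([[1.0, 2.0, 3.0], [-2.0, -4.0, -6.0]]))
        assert d[0] == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_pearson_formula(self):
        rows = [[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]]
        d = class_distances(meta(rows))
        r = brute_pearson(rows[0], rows[1])
        assert r == pytest.approx(0.9819805060619659, abs=1e-12)
        assert d[0] == pytest.approx(1.0 - r, abs=1e-12)

    def test_constant_row_distance_one_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            d = class_distances(meta([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]))
        D = squareform(d)
        assert D[0, 1] == 1.0 and D[0, 2] == 1.0
        assert D[1, 2] == pytest.approx(2.0)


class TestSingleLinkage:
    def test_three_item_example(self):
        # d(0,1)=0.1, d(0,2)=0.9, d(1,2)=0.8
        tree = single_linkage(np.array([0.1, 0.9, 0.8]))
        assert tree[0, 2] == pytest.approx(0.1)
        assert set(tree[0, :2].astype(int)) == {0, 1}
        assert tree[1, 2] == pytest.approx(0.8)

    def test_equidistant_merges_at_common_height(self):
        tree = single_linkage(np.array([0.4, 0.4, 0.4]))
        np.testing.assert_allclose(tree[:, 2], [0.4, 0.4])

    def test_merge_count(self, rng):
        n = 9
        d = rng.uniform(0.1, 1.0, size=n * (n - 1) // 2)
        assert single_linkage(d).shape == (n - 1, 4)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            single_linkage(np.array([]))


class TestCopheneticDistances:
    def test_three_item_example(self):
        tree = single_linkage(np.array([0.1, 0.9, 0.8]))
        coph = cophenetic_distances(tree)
        np.testing.assert_allclose(coph, [0.1, 0.8, 0.8])

    def test_first_merged_pair_height(self, rng):
        n = 7
        d = rng.uniform(0.1, 1.0, size=n * (n - 1) // 2)
        tree = single_linkage(d)
        coph = squareform(cophenetic_distances(tree))
        i, j = sorted(tree[0, :2].astype(int))
        assert coph[i, j] == pytest.approx(tree[0, 2])

    def test_ultrametric_three_point_condition(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            d = rng.uniform(0.1, 1.0, size=n * (n - 1) // 2)
            C = squareform(cophenetic_distances(single_linkage(d)))
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        if len({i, j, k}) == 3:
                            assert C[i, k] <= max(C[i, j], C[j, k]) + 1e-12


class TestCopheneticCC:
    def test_ultrametric_fixed_point(self, rng):
        d = np.array(random_ultrametric(rng, 8))
        tree = single_linkage(d)
        ccc = cophenetic_cc(d, cophenetic_distances(tree))
        assert ccc == pytest.approx(1.0, abs=1e-12)

    def test_three_item_example_vs_pearson_oracle(self):
        orig = np.array([0.1, 0.9, 0.8])
        tree = single_linkage(orig)
        coph = cophenetic_distances(tree)
        want = brute_pearson([0.1, 0.9, 0.8], [0.1, 0.8, 0.8])
        assert cophenetic_cc(orig, coph) == pytest.approx(want, abs=1e-12)

    def test_common_permutation_invariance(self, rng):
        x = rng.uniform(0, 1, 15)
        y = rng.uniform(0, 1, 15)
        perm = rng.permutation(15)
        assert cophenetic_cc(x, y) == pytest.approx(cophenetic_cc(x[perm], y[perm]), abs=1e-12)

    def test_constant_vector_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(cophenetic_cc(np.ones(3), np.array([0.1, 0.2, 0.3])))


@settings(deadline=None, max_examples=60)
@given(st.integers(min_value=0, max_value=2**32 - 1), st.integers(min_value=3, max_value=12))
def test_pipeline_matches_brute_force_oracle(seed, n):
    """single linkage + cophenetic + CC_c equals naive agglomeration/LCA/Pearson."""
    r = np.random.default_rng(seed)
    d = r.uniform(0.05, 1.0, size=n * (n - 1) // 2)
    tree = single_linkage(d)
    got = cophenetic_cc(d, cophenetic_distances(tree))
    want = brute_ccc(d.tolist(), n)
    assert got == pytest.approx(want, abs=1e-10)
    # heights of the merge sequence agree with brute force agglomeration
    merges = brute_single_linkage(d.tolist(), n)
    np.testing.assert_allclose(sorted(tree[:, 2]), sorted(m[2] for m in merges), atol=1e-12)


class TestScan:
    def test_relabeling_invariance_of_ccc(self, rng):
        vals = rng.standard_normal((10, 4))
        base = ccc_of_metadata(meta(vals))
        perm = rng.permutation(10)
        assert ccc_of_metadata(meta(vals[perm])) == pytest.approx(base, abs=1e-12)

    def test_single_element_grid_is_argmax(self, small_ma, small_corpus):
        res = scan_model_orders(small_ma, small_corpus.label_matrix, [4], seed=3)
        assert res.argmax_d == 4
        assert len(res.ccc_values) == 1

    def test_same_seed_identical_curves(self, small_ma, small_corpus):
        a = scan_model_orders(small_ma, small_corpus.label_matrix, [3, 4, 5], seed=9)
        b = scan_model_orders(small_ma, small_corpus.label_matrix, [3, 4, 5], seed=9)
        np.testing.assert_array_equal(a.ccc_values, b.ccc_values)
        assert a.selected_orders == b.selected_orders

    def test_degenerate_low_orders_flagged_and_excluded(self, small_ma, small_corpus):
        res = scan_model_orders(small_ma, small_corpus.label_matrix, [2, 3, 4], seed=9)
        assert res.degenerate_orders == [2]
        # d=2 distances are all 0 or 2, so its dendrogram fits them exactly
        assert res.ccc_values[0] == pytest.approx(1.0, abs=1e-12)
        assert res.argmax_d != 2

    def test_failed_order_recorded_and_scan_continues(self, small_corpus, rng):
        # rank-deficient matrix: d above the rank fails, the rest completes
        low_rank = rng.standard_normal((120, 5)) @ rng.exponential(size=(5, 2000))
        res = scan_model_orders(low_rank, small_corpus.label_matrix, [3, 50], seed=1)
        assert 50 in res.diagnostics
        assert np.isfinite(res.ccc_values[0])

    def test_grid_exceeding_e_rejected(self, small_ma, small_corpus):
        with pytest.raises(ValueError):
            scan_model_orders(small_ma, small_corpus.label_matrix, [500], seed=0)
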