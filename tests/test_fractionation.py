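import math

import numpy as np
import pytest

from coactnet.fractionation import (
    ARTIFACT,
    CrossCorrMatrix,
    ParentAssignment,
    assign_parents,
    flag_artifacts,
    network_hca,
    spatial_cross_correlation,
    summarize_fractionation,
)
from coactnet.ica_decomp import ZMaps
from coactnet.metaproject import MetadataMatrix
from oracles import brute_pearson


def zmaps(arr):
    arr = np.asarray(arr, dtype=float)
    return ZMaps(zvalues=arr, threshold=4.0, background_fit=[{}] * len(arr))


def meta(values):
    values = np.asarray(values, dtype=float)
    return MetadataMatrix(values=values, class_names=[f"c{i}" for i in range(len(values))],
                          d=values.shape[1])


class TestSpatialCrossCorrelation:
    def test_self_correlation_is_one(self, rng):
        m = rng.standard_normal((3, 500))
        cc = spatial_cross_correlation(zmaps(m), zmaps(m))
        np.testing.assert_allclose(np.diag(cc.values), 1.0, atol=1e-12)

    def test_positive_rescaling_invariance(self, rng):
        a = rng.standard_normal((2, 300))
        b = rng.standard_normal((4, 300))
        base = spatial_cross_correlation(zmaps(a), zmaps(b)).values
        scaled = spatial_cross_correlation(zmaps(a * 7.3), zmaps(b)).values
        np.testing.assert_allclose(scaled, base, atol=1e-12)

    def test_disjoint_supports_vs_brute_pearson(self):
        v = 2000
        a = np.zeros((1, v))
        b = np.zeros((1, v))
        a[0, 100:140] = np.linspace(1, 8, 40)
        b[0, 1500:1560] = np.linspace(2, 5, 60)
        got = spatial_cross_correlation(zmaps(a), zmaps(b)).values[0, 0]
        want = brute_pearson(a[0].tolist(), b[0].tolist())
        assert got == pytest.approx(want, abs=1e-12)

    def test_voxel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            spatial_cross_correlation(zmaps(rng.standard_normal((2, 50))),
                                      zmaps(rng.standard_normal((2, 60))))

    def test_constant_map_yields_nan(self, rng):
        a = np.vstack([np.ones(100), rng.standard_normal(100)])
        with pytest.warns(UserWarning):
            cc = spatial_cross_correlation(zmaps(a), zmaps(rng.standard_normal((2, 100))))
        assert np.isnan(cc.values[0]).all()
        assert np.isfinite(cc.values[1]).all()


class TestAssignParents:
    def test_argmax_assignment(self):
        cc = CrossCorrMatrix(values=np.array([[0.9, 0.1, 0.2], [0.3, 0.8, 0.1]]),
                             high_ids=[0, 1], low_ids=[0, 1, 2])
        a = assign_parents(cc)
        np.testing.assert_array_equal(a.parent, [0, 1])
        np.testing.assert_allclose(a.correlation, [0.9, 0.8])

    def test_artifact_high_excluded(self):
        cc = CrossCorrMatrix(values=np.array([[0.9, 0.1], [0.3, 0.8]]),
                             high_ids=[0, 1], low_ids=[0, 1])
        a = assign_parents(cc, artifact_high=[0])
        assert a.parent[0] == ARTIFACT
        assert np.isnan(a.correlation[0])
        assert a.parent[1] == 1

    def test_artifact_low_excluded_from_argmax(self):
        cc = CrossCorrMatrix(values=np.array([[0.9, 0.5]]), high_ids=[0], low_ids=[0, 1])
        a = assign_parents(cc, artifact_low=[0])
        assert a.parent[0] == 1

    def test_exact_tie_takes_lower_id(self):
        cc = CrossCorrMatrix(values=np.array([[0.5, 0.5]]), high_ids=[0], low_ids=[0, 1])
        assert assign_parents(cc).parent[0] == 0

    def test_all_low_artifacts_rejected(self):
        cc = CrossCorrMatrix(values=np.array([[0.5, 0.5]]), high_ids=[0], low_ids=[0, 1])
        with pytest.raises(ValueError):
            assign_parents(cc, artifact_low=[0, 1])

    def test_row_reordering_invariance(self, rng):
        vals = rng.uniform(-1, 1, size=(5, 4))
        cc = CrossCorrMatrix(values=vals, high_ids=list(range(5)), low_ids=list(range(4)))
        base = assign_parents(cc, artifact_high=[2])
        perm = rng.permutation(5)
        cc2 = CrossCorrMatrix(values=vals[perm], high_ids=list(range(5)), low_ids=list(range(4)))
        other = assign_parents(cc2, artifact_high=[int(np.flatnonzero(perm == 2)[0])])
        np.testing.assert_array_equal(other.parent, base.parent[perm])


class TestNetworkHca:
    def test_duplicate_columns_merge_at_zero(self, rng):
        col = rng.standard_normal(6)
        vals = np.column_stack([col, col, rng.standard_normal(6)])
        tree = network_hca(meta(vals))
        assert tree[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(tree[0, :2].astype(int)) == {0, 1}

    def test_merge_count(self, rng):
        tree = network_hca(meta(rng.standard_normal((8, 5))))
        assert tree.shape == (4, 4)

    def test_planted_family_structure(self, rng):
        """Components from the same label family merge before any cross-family merge."""
        base1 = np.abs(rng.standard_normal(12))
        base2 = np.abs(rng.standard_normal(12))
        cols = []
        for base, n in ((base1, 3), (base2, 3)):
            for _ in range(n):
                cols.append(base + rng.normal(0, 0.01, 12))
        vals = np.column_stack(cols)
        tree = network_hca(meta(vals))
        # the first four merges stay within {0,1,2} or {3,4,5}
        n = vals.shape[1]
        members = {i: {i} for i in range(n)}
        next_id = n
        for left, right, h, _ in tree[:-1]:
            s = members[int(left)] | members[int(right)]
            assert s <= {0, 1, 2} or s <= {3, 4, 5}
            members[next_id] = s
            next_id += 1


class TestFlagArtifacts:
    def test_uniform_column_flagged(self):
        vals = np.column_stack([np.full(20, 0.7), np.eye(20)[:, 0]])
        flagged = flag_artifacts(meta(vals), uniformity_threshold=0.95)
        assert flagged == [0]

    def test_one_hot_never_flagged(self):
        vals = np.eye(20)[:, :3]
        assert flag_artifacts(meta(vals), uniformity_threshold=0.0) == []
        # entropy of a one-hot column is exactly 0

    def test_dominant_class_entropy_vs_explicit_formula(self):
        w = np.ones(20)
        w[0] = 10.0
        p = w / w.sum()
        h = -(p * np.log(p)).sum() / math.log(20)
        vals = np.column_stack([np.ones(20), w])
        flagged = flag_artifacts(meta(vals), uniformity_threshold=0.95)
        assert h < 0.95  # the dominant-class column stays below the threshold
        assert flagged == [0]

    def test_manual_overrides(self):
        vals = np.column_stack([np.ones(10), np.eye(10)[:, 0]])
        assert flag_artifacts(meta(vals), 0.95, include=[1]) == [0, 1]
        assert flag_artifacts(meta(vals), 0.95, exclude=[0]) == []


def test_planted_subblob_fractionation_recovers_rate_m(coarse_grid):
    """k planted networks of m blobs each: every blob map is assigned to its
    own network's map and each group's fractionation rate is exactly m."""
    from coactnet.maimage import modeled_activation
    from coactnet.synthcorpus import SynthConfig, make_ground_truth

    k, m = 4, 3
    cfg = SynthConfig(k_networks=k, blobs_per_network=(m, m), peak_jitter_sd=0.0,
                      min_network_separation=80.0, blob_scatter_mm=18.0, seed=5)
    nets = make_ground_truth(cfg, coarse_grid)
    low = np.array([
        modeled_activation(n.blob_centers, coarse_grid, fwhm=12.0)[coarse_grid.mask]
        for n in nets
    ])
    high = np.array([
        modeled_activation([bc], coarse_grid, fwhm=12.0)[coarse_grid.mask]
        for n in nets for bc in n.blob_centers
    ])
    cc = spatial_cross_correlation(zmaps(high), zmaps(low))
    assignment = assign_parents(cc)
    summary = summarize_fractionation(assignment, {j: f"net_{j}" for j in range(k)})
    assert all(r == pytest.approx(float(m)) for r in summary.rate.values())


class TestSummarizeFractionation:
    def test_printed_rates(self):
        # 5 parents with 20 assigned children -> 4.0; 6 with 23 -> 3.83
        parent = np.array([0] * 4 + [1] * 4 + [2] * 4 + [3] * 4 + [4] * 4
                          + [5] * 4 + [6] * 4 + [7] * 4 + [8] * 4 + [9] * 4 + [10] * 3)
        groups = {i: "emotional" for i in range(5)}
        groups.update({i: "cognitive" for i in range(5, 11)})
        a = ParentAssignment(parent=parent, correlation=np.ones(len(parent)))
        s = summarize_fractionation(a, groups)
        assert s.n_parents == {"cognitive": 6, "emotional": 5}
        assert s.n_subnetworks == {"cognitive": 23, "emotional": 20}
        assert s.rate_2dp["emotional"] == pytest.approx(4.0)
        assert s.rate_2dp["cognitive"] == pytest.approx(3.83)

    def test_zero_children_rate_zero(self):
        a = ParentAssignment(parent=np.array([0, 0]), correlation=np.ones(2))
        s = summarize_fractionation(a, {0: "g0", 1: "g1"})
        assert s.rate["g1"] == 0.0

    def test_unknown_parent_group_rejected(self):
        a = ParentAssignment(parent=np.array([3]), correlation=np.ones(1))
        with pytest.raises(KeyError):
            summarize_fractionation(a, {0: "g"})

    def test_subnetworks_plus_artifacts_account_for_all_high_components(self, rng):
        d_high, d_low = 12, 4
        vals = rng.uniform(-1, 1, size=(d_high, d_low))
        cc = CrossCorrMatrix(values=vals, high_ids=list(range(d_high)),
                             low_ids=list(range(d_low)))
        artifacts = [1, 7]
        a = assign_parents(cc, artifact_high=artifacts)
        s = summarize_fractionation(a, {j: f"g{j}" for j in range(d_low)})
        assert sum(s.n_subnetworks.values()) + len(artifacts) == d_high
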