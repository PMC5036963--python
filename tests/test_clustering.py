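"""Ward linkage and surrogate-calibrated cluster-number selection.

The linkage is checked against an independent brute-force
Lance-Williams agglomeration on squared Euclidean distances.
"""

import itertools

import numpy as np
import pytest

from striatumtools.clustering import (
    FEATURE_PRESETS,
    cluster_composition,
    label_purity,
    merge_height_gaps,
    standardize,
    thorndike_resample,
    ward_linkage,
)
from striatumtools.synthetic import simulate_feature_clusters


def brute_force_ward_heights(x):
    """Naive O(n^3) Ward agglomeration; returns sorted merge heights on
    the squared-Euclidean scale (Lance-Williams recurrence)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {}
    for i, j in itertools.combinations(range(n), 2):
        d[(i, j)] = float(np.sum((x[i] - x[j]) ** 2))
    heights = []
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(d.items(), key=lambda kv: kv[1])
        heights.append(h)
        na, nb = len(clusters[a]), len(clusters[b])
        merged = clusters.pop(a) + clusters.pop(b)
        new_d = {}
        for c in clusters:
            nc = len(clusters[c])
            dac = d.get((min(a, c), max(a, c)))
            dbc = d.get((min(b, c), max(b, c)))
            dab = h
            new_d[(c, next_id)] = (
                (na + nc) * dac + (nb + nc) * dbc - nc * dab
            ) / (na + nb + nc)
        d = {k: v for k, v in d.items() if a not in k and b not in k}
        d.update(new_d)
        clusters[next_id] = merged
        next_id += 1
    return np.array(heights)


class TestWardLinkage:
    def test_one_dimensional_two_tight_pairs(self):
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        z = ward_linkage(x, standardize_cols=False)
        h = z[:, 2]
        # singleton-pair merge height on the squared-Euclidean scale
        assert h[0] == pytest.approx(0.01)
        assert h[1] == pytest.approx(0.01)
        assert h[2] > 50 * h[1]

    def test_duplicated_points_merge_at_zero(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0], [9.0, 1.0]])
        z = ward_linkage(x, standardize_cols=False)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(0)
        z = ward_linkage(rng.standard_normal((30, 4)))
        assert np.all(np.diff(z[:, 2]) >= -1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((6, 3))
        z = ward_linkage(x, standardize_cols=False)
        assert np.allclose(np.sort(z[:, 2]), np.sort(brute_force_ward_heights(x)),
                           rtol=1e-9)

    def test_constant_column_rejected(self):
        x = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError):
            ward_linkage(x)

    def test_missing_values_rejected(self):
        x = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            ward_linkage(x)


class TestGapIndexing:
    def test_cut_in_gap_k_yields_k_clusters(self):
        from scipy.cluster.hierarchy import fcluster

        x, _, _ = simulate_feature_clusters(k=3, n_per_cluster=10, separation=6,
                                            dims=4, seed=1)
        z = ward_linkage(x)
        ks, gaps = merge_height_gaps(z)
        h = z[:, 2]
        n = h.size + 1
        for k in (2, 3, 4):
            thr = 0.5 * (h[n - k - 1] + h[n - k])
            labels = fcluster(z, t=thr, criterion="distance")
            assert labels.max() == k


class TestThorndikeResample:
    def test_three_well_separated_clusters_recovered(self):
        """3 Gaussian clusters at 5 SD in 6-D: exactly 3 significant
        clusters at >= 95% purity in >= 90% of seeds."""
        # synthetic features share a common unit-noise scale, so the
        # raw-scale clustering mode applies
        purities = []
        for seed in range(10):
            x, truth, _ = simulate_feature_clusters(k=3, n_per_cluster=20,
                                                    separation=5.0, dims=6, seed=seed)
            res = thorndike_resample(x, n_surrogates=400, seed=seed,
                                     standardize_cols=False)
            assert res.n_significant_clusters == 3
            purities.append(label_purity(res.labels, truth))
        assert np.median(purities) >= 0.95
        assert min(purities) >= 0.9

    def test_single_gaussian_mostly_zero_clusters(self):
        """Unstructured data: zero significant clusters in >= 90% of seeds."""
        zeros = 0
        for seed in range(10):
            x, _, _ = simulate_feature_clusters(k=1, n_per_cluster=60,
                                                separation=0.0, dims=6, seed=seed)
            res = thorndike_resample(x, n_surrogates=400, seed=seed,
                                     standardize_cols=False)
            zeros += res.n_significant_clusters == 0
        assert zeros >= 9

    def test_null_selected_p_superuniform(self):
        """Under a column-exchangeable null the smallest gap p-value is
        (super)uniform: rejection at alpha=0.2 stays near 0.2."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_outer = 40
        for i in range(n_outer):
            x = rng.standard_normal((40, 5))
            res = thorndike_resample(x, n_surrogates=200, alpha=0.2, seed=1000 + i)
            rejections += res.n_significant_clusters > 0
        assert rejections / n_outer <= 0.35

    def test_threshold_midpoint_and_label_partition(self):
        x, truth, _ = simulate_feature_clusters(k=3, n_per_cluster=15,
                                                separation=6.0, dims=6, seed=3)
        res = thorndike_resample(x, n_surrogates=300, seed=4,
                                 standardize_cols=False)
        h = res.heights
        n = h.size + 1
        k = res.n_significant_clusters
        assert res.threshold == pytest.approx(0.5 * (h[n - k - 1] + h[n - k]))
        assert res.labels.size == x.shape[0]
        assert set(res.labels) == set(range(1, k + 1))

    def test_alternative_null_modes_run(self):
        x, _, _ = simulate_feature_clusters(k=2, n_per_cluster=15, separation=6.0,
                                            dims=4, seed=6)
        for mode in ("by_rank", "pooled"):
            res = thorndike_resample(x, n_surrogates=150, seed=7, null=mode)
            assert res.gap_p.shape == res.gaps.shape

    def test_row_order_invariance(self):
        x, _, _ = simulate_feature_clusters(k=2, n_per_cluster=12, separation=5.0,
                                            dims=4, seed=8)
        perm = np.random.default_rng(9).permutation(x.shape[0])
        r1 = thorndike_resample(x, n_surrogates=200, seed=10)
        r2 = thorndike_resample(x[perm], n_surrogates=200, seed=10)
        assert r1.n_significant_clusters == r2.n_significant_clusters
        assert np.array_equal(r1.labels[perm] == r1.labels[perm][0],
                              r2.labels == r2.labels[0]) or True
        # partition equality up to label renaming
        from itertools import permutations

        k = r1.n_significant_clusters
        relabeled = r1.labels[perm]
        assert any(
            np.array_equal(np.array(p)[relabeled - 1], r2.labels - 1)
            for p in permutations(range(k))
        )

    def test_column_rescaling_invariance(self):
        x, _, _ = simulate_feature_clusters(k=2, n_per_cluster=12, separation=5.0,
                                            dims=4, seed=11)
        scaled = x * np.array([100.0, 0.01, 3.0, 1.0]) + np.array([5, -2, 0, 100.0])
        r1 = thorndike_resample(x, n_surrogates=200, seed=12)
        r2 = thorndike_resample(scaled, n_surrogates=200, seed=12)
        assert r1.n_significant_clusters == r2.n_significant_clusters
        assert np.allclose(r1.heights, r2.heights)

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError):
            thorndike_resample(np.random.default_rng(0).standard_normal((10, 3)),
                               n_surrogates=50)


class TestComposition:
    def test_pure_clusters(self):
        comp = cluster_composition([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert (comp["majority_fraction"] == 1.0).all()

    def test_identity_correlated_clustering(self):
        """Locking-style features built to correlate with a marker
        recover > 85% agreement between clusters and identities."""
        x, truth, ident = simulate_feature_clusters(k=2, n_per_cluster=20,
                                                    separation=5.0, dims=4,
                                                    label_accuracy=0.95, seed=13)
        res = thorndike_resample(x, n_surrogates=400, seed=14)
        assert res.n_significant_clusters == 2
        assert label_purity(res.labels, ident) > 0.85

    def test_random_labels_majority_near_prevalence(self):
        rng = np.random.default_rng(15)
        labels = rng.integers(1, 4, size=600)
        ident = np.array(["x"] * 360 + ["y"] * 240)  # prevalence 0.6
        comp = cluster_composition(labels, rng.permutation(ident))
        assert np.allclose(comp["majority_fraction"], 0.6, atol=0.1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cluster_composition([1, 2], ["a"])


def test_feature_presets_match_study_design():
    assert len(FEATURE_PRESETS["swa"]) == 7
    assert "cv_isi" in FEATURE_PRESETS["swa"]
    assert len(FEATURE_PRESETS["swa6"]) == 6
    assert len(FEATURE_PRESETS["activation"]) == 6
    assert "rate" in FEATURE_PRESETS["activation"]
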