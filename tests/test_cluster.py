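"""Double hierarchical clustering: distances, Ward trees, diagnostics, profiles."""

import warnings

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster

from immunoprofiles.cluster import (
    assign_profiles,
    choose_k,
    double_clustering,
    heatmap_export,
    hopkins,
    marker_distance,
    patient_distance,
    profiling_marker_ids,
    ward_linkage,
    zscore_markers,
    _mean_silhouette,
)
from tests.conftest import make_table


def blobs(rng, centers, n_each, sd=0.3):
    parts = [rng.normal(c, sd, size=(n_each, len(c))) for c in centers]
    labels = np.repeat(np.arange(len(centers)), n_each)
    return np.vstack(parts), labels


class TestZScore:
    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.normal(50, 20, (40, 3)))
        Z, ids = zscore_markers(table)
        assert ids == table.marker_ids()
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-10)

    def test_constant_column_dropped_with_warning(self):
        vals = np.column_stack([np.arange(10.0), np.full(10, 7.0)])
        table = make_table(vals)
        with pytest.warns(UserWarning, match="zero-variance"):
            Z, ids = zscore_markers(table)
        assert ids == ["m0"]
        assert Z.shape == (10, 1)

    def test_profiling_markers_exclude_counts(self, profile_cohort):
        table, _, _ = profile_cohort
        ids = profiling_marker_ids(table)
        assert all(not i.endswith("_cnt") for i in ids)
        assert {"sCD163", "sTNFRI", "tPA", "sEPCR"} <= set(ids)


class TestDistances:
    def test_identical_rows_at_distance_zero(self):
        Z = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        D = patient_distance(Z)
        assert D[0, 1] == 0.0

    def test_three_four_five_triangle(self):
        D = patient_distance(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == pytest.approx(5.0)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(60, 5))
        D = patient_distance(Z)
        idx = rng.integers(0, 60, size=(1000, 3))
        for i, j, k in idx:
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-9

    def test_marker_self_distance_zero_and_negation_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        Z = np.column_stack([x, -x, rng.normal(size=100)])
        D = marker_distance(Z)
        assert D[0, 0] == 0.0
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_independent_markers_near_distance_one(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(10_000, 2))
        D = marker_distance(Z)
        assert D[0, 1] > 0.95

    def test_zero_variance_marker_rejected(self):
        Z = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            marker_distance(Z)


def brute_force_ward(D):
    """Naive O(n^3) Ward via Lance-Williams on squared dissimilarities.

    Returns the sorted sequence of merge heights (on the distance scale).
    """
    D2 = D.astype(float) ** 2
    active = {i: 1 for i in range(len(D))}
    d2 = {(i, j): D2[i, j] for i in range(len(D)) for j in range(i + 1, len(D))}

    def get(i, j):
        return d2[(min(i, j), max(i, j))]

    heights = []
    next_id = len(D)
    while len(active) > 1:
        (i, j) = min(
            ((a, b) for a in active for b in active if a < b), key=lambda t: get(*t)
        )
        h2 = get(i, j)
        heights.append(np.sqrt(h2))
        ni, nj = active[i], active[j]
        new = {}
        for k in active:
            if k in (i, j):
                continue
            nk = active[k]
            tot = ni + nj + nk
            new[k] = (
                (ni + nk) / tot * get(i, k)
                + (nj + nk) / tot * get(j, k)
                - nk / tot * h2
            )
        del active[i], active[j]
        active[next_id] = ni + nj
        for k, v in new.items():
            d2[(min(k, next_id), max(k, next_id))] = v
        next_id += 1
    return np.array(heights)


class TestWardLinkage:
    def test_nearest_pair_merges_first_on_a_line(self):
        D = patient_distance(np.array([[0.0], [1.0], [10.0]]))
        tree = ward_linkage(D)
        assert set(tree[0, :2].astype(int)) == {0, 1}

    def test_two_blobs_recovered_exactly_at_k2(self):
        rng = np.random.default_rng(4)
        Z, truth = blobs(rng, [(0, 0), (10, 10)], 10)
        tree = ward_linkage(patient_distance(Z))
        labels = fcluster(tree, t=2, criterion="maxclust")
        assert len(set(zip(truth, labels))) == 2  # one-to-one blocks

    def test_merge_heights_match_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = int(rng.integers(4, 8))
            Z = rng.normal(size=(n, 3))
            D = patient_distance(Z)
            tree = ward_linkage(D)
            np.testing.assert_allclose(
                np.sort(tree[:, 2]), np.sort(brute_force_ward(D)), rtol=1e-8
            )

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(6)
        for seed in range(5):
            Z = rng.normal(size=(30, 4))
            tree = ward_linkage(patient_distance(Z))
            assert np.all(np.diff(tree[:, 2]) >= -1e-10)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ward_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestHopkins:
    def test_uniform_null_concentrates_near_half(self):
        rng = np.random.default_rng(12345)
        inside = 0
        for s in range(100):
            Z = rng.uniform(size=(200, 10))
            h = hopkins(Z, seed=s + 7)
            inside += 0.4 < h < 0.6
        assert inside >= 90

    def test_two_tight_distant_blobs_score_high(self):
        rng = np.random.default_rng(8)
        Z, _ = blobs(rng, [(0,) * 5, (5,) * 5], 50, sd=0.05)
        assert hopkins(Z, seed=1) > 0.8

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        Z = rng.normal(size=(50, 3))
        assert hopkins(Z, seed=4) == hopkins(Z, seed=4)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            hopkins(np.zeros((10, 2)))


class TestChooseK:
    def test_three_separated_blobs_found_by_both_criteria(self):
        rng = np.random.default_rng(10)
        Z, _ = blobs(rng, [(0, 0), (8, 0), (0, 8)], 20)
        D = patient_distance(Z)
        res = choose_k(Z, D, k_range=range(2, 7), B=20, seed=0)
        assert res.k_sil == 3
        assert res.k_gap == 3
        assert res.k == 3

    def test_degenerate_k_range(self):
        rng = np.random.default_rng(11)
        Z = rng.normal(size=(30, 2))
        res = choose_k(Z, patient_distance(Z), k_range=range(2, 3), B=10, seed=0)
        assert res.k == 2

    def test_silhouette_matches_sklearn_reference(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(12)
        Z, _ = blobs(rng, [(0, 0), (4, 4)], 15)
        D = patient_distance(Z)
        labels = fcluster(ward_linkage(D), t=2, criterion="maxclust")
        ours = _mean_silhouette(D, labels)
        ref = silhouette_score(D, labels, metric="precomputed")
        assert ours == pytest.approx(ref, abs=1e-10)


class TestAssignProfiles:
    def test_every_patient_its_own_profile_at_k_equals_n(self):
        rng = np.random.default_rng(13)
        Z = rng.normal(size=(8, 2))
        tree = ward_linkage(patient_distance(Z))
        labels = assign_profiles(tree, 8)
        assert sorted(labels) == list(range(1, 9))

    def test_blob_memberships_at_k2(self):
        rng = np.random.default_rng(14)
        Z, truth = blobs(rng, [(0, 0), (9, 9)], 12)
        tree = ward_linkage(patient_distance(Z))
        labels = assign_profiles(tree, 2)
        assert len(set(zip(truth, labels))) == 2

    def test_labels_numbered_by_decreasing_size(self):
        rng = np.random.default_rng(15)
        Z = np.vstack([rng.normal(0, 0.2, (20, 2)), rng.normal(8, 0.2, (5, 2))])
        tree = ward_linkage(patient_distance(Z))
        labels = assign_profiles(tree, 2)
        assert (labels == 1).sum() == 20
        assert (labels == 2).sum() == 5

    def test_k_larger_than_n_rejected(self):
        Z = np.random.default_rng(16).normal(size=(5, 2))
        tree = ward_linkage(patient_distance(Z))
        with pytest.raises(ValueError):
            assign_profiles(tree, 6)


class TestProfileRecovery:
    def test_planted_profiles_recovered_with_high_ari(self):
        """Adjusted Rand between k=6 labels and planted profiles >= 0.7 in
        >= 80% of seeds on default generator cohorts."""
        from sklearn.metrics import adjusted_rand_score

        from immunoprofiles.preprocess import (
            dedup_correlated,
            drop_high_missing,
            impute_knn2,
        )
        from immunoprofiles.synth import GeneratorConfig, generate_profile_cohort

        good = 0
        n_seeds = 12
        for seed in range(n_seeds):
            table, ann, truth = generate_profile_cohort(GeneratorConfig(seed=seed))
            table, _ = drop_high_missing(table)
            table, _ = impute_knn2(table)
            table, _ = dedup_correlated(table, ann)
            sub = table.select_markers(profiling_marker_ids(table))
            Z, _ = zscore_markers(sub)
            tree = ward_linkage(patient_distance(Z))
            labels = assign_profiles(tree, 6)
            good += adjusted_rand_score(truth.true_profile, labels) >= 0.7
        assert good >= 0.8 * n_seeds

    def test_cutting_at_smaller_k_only_merges_clusters(self, profile_cohort):
        table, _, _ = profile_cohort
        from immunoprofiles.preprocess import drop_high_missing, impute_knn2

        t, _ = drop_high_missing(table)
        t, _ = impute_knn2(t)
        Z, _ = zscore_markers(t.select_markers(profiling_marker_ids(t)))
        tree = ward_linkage(patient_distance(Z))
        for k in range(3, 9):
            fine = fcluster(tree, t=k, criterion="maxclust")
            coarse = fcluster(tree, t=k - 1, criterion="maxclust")
            # each fine cluster maps into exactly one coarse cluster
            for c in np.unique(fine):
                assert len(np.unique(coarse[fine == c])) == 1


class TestHeatmapExport:
    def test_ordered_tsv_follows_dendrogram_and_is_reproducible(self, tmp_path):
        rng = np.random.default_rng(17)
        table = make_table(rng.normal(50, 10, (15, 4)))
        res = double_clustering(table, k_range=range(2, 5), B=5, seed=0)
        p1, m1 = tmp_path / "h1.png", tmp_path / "m1.tsv"
        p2, m2 = tmp_path / "h2.png", tmp_path / "m2.tsv"
        heatmap_export(res, p1, m1)
        heatmap_export(res, p2, m2)
        assert m1.read_bytes() == m2.read_bytes()
        from scipy.cluster.hierarchy import dendrogram

        leaves = dendrogram(res.patient_tree, no_plot=True)["leaves"]
        first_col = [
            line.split("\t")[0] for line in m1.read_text().splitlines()[1:]
        ]
        assert first_col == [res.patient_ids[i] for i in leaves]

    def test_two_by_two_degenerate_matrix(self, tmp_path):
        table = make_table([[1.0, 5.0], [2.0, 3.0], [8.0, 1.0]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = double_clustering(table, k_range=range(2, 3), B=3, seed=0)
        heatmap_export(res, tmp_path / "h.png", tmp_path / "m.tsv")
        assert (tmp_path / "h.png").exists()
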