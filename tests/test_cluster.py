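import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn import metrics as skmetrics
from sklearn.metrics import adjusted_rand_score

from deepsubtype.cluster import (
    DEFAULT_METHODS,
    compare_methods,
    davies_bouldin,
    kmeans_cluster,
    select_k,
    silhouette_score,
)
from deepsubtype.exceptions import ConfigurationError, UndefinedMetricError

from conftest import tiny_dae_config


def brute_silhouette(points, labels):
    """Quadratic-loop silhouette, independent of the package implementation."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] != len(labels):
        pts = pts.T
    lab = np.asarray(labels)
    scores = []
    for i in range(len(lab)):
        same = [j for j in range(len(lab)) if lab[j] == lab[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(pts[i] - pts[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(pts[i] - pts[j]) for j in range(len(lab)) if lab[j] == c])
            for c in set(lab) - {lab[i]}
        )
        scores.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(scores))


def brute_dbi(points, labels):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    lab = np.asarray(labels)
    cl = sorted(set(lab))
    cents = {c: pts[lab == c].mean(axis=0) for c in cl}
    s = {c: np.mean([np.linalg.norm(p - cents[c]) for p in pts[lab == c]]) for c in cl}
    worst = []
    for i in cl:
        ratios = []
        for j in cl:
            if i == j:
                continue
            m = np.linalg.norm(cents[i] - cents[j])
            ratios.append(np.inf if m == 0 else (s[i] + s[j]) / m)
        worst.append(max(ratios))
    return float(np.mean(worst))


TWO_PAIRS = np.array([[0.0], [0.1], [10.0], [10.1]])
TWO_PAIRS_LABELS = np.array([0, 0, 1, 1])


class TestSilhouette:
    def test_two_separated_pairs_hand_value(self):
        # outer points (0, 10.1): a = 0.1, b = (9.9+10.1)/2 = 10.05 -> s = 9.95/10.05
        # inner points (0.1, 10): a = 0.1, b = (9.9+10.0)/2 =  9.95 -> s = 9.85/9.95
        expected = 0.5 * (9.95 / 10.05 + 9.85 / 9.95)
        got = silhouette_score(TWO_PAIRS, TWO_PAIRS_LABELS)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.99, abs=1e-3)

    def test_identical_points_score_zero_by_convention(self):
        pts = np.zeros((6, 2))
        assert silhouette_score(pts, [0, 0, 0, 1, 1, 1]) == 0.0

    def test_singleton_cluster_contributes_zero(self):
        pts = np.array([[0.0], [0.1], [5.0]])
        lab = np.array([0, 0, 1])
        assert silhouette_score(pts, lab) == pytest.approx(brute_silhouette(pts, lab), abs=1e-12)

    def test_matches_brute_force_and_sklearn_on_random_instances(self, rng):
        for _ in range(50):
            n, k = int(rng.integers(8, 30)), int(rng.integers(2, 5))
            pts = rng.normal(size=(n, 2))
            lab = rng.integers(0, k, size=n)
            if len(np.unique(lab)) < 2:
                continue
            ours = silhouette_score(pts, lab)
            assert ours == pytest.approx(brute_silhouette(pts, lab), abs=1e-9)
            assert ours == pytest.approx(skmetrics.silhouette_score(pts, lab), abs=1e-9)

    def test_single_cluster_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            silhouette_score(np.zeros((4, 2)), [0, 0, 0, 0])

    def test_invariant_to_label_permutation_and_translation(self, rng):
        pts = rng.normal(size=(20, 3))
        lab = rng.integers(0, 3, size=20)
        base = silhouette_score(pts, lab)
        assert silhouette_score(pts + 100.0, lab) == pytest.approx(base, abs=1e-9)
        assert silhouette_score(pts, 2 - lab) == pytest.approx(base, abs=1e-9)


class TestDaviesBouldin:
    def test_two_separated_pairs_hand_value(self):
        # s_i = 0.05 each, centroid distance 10 -> DBI = (0.05+0.05)/10 = 0.01
        assert davies_bouldin(TWO_PAIRS, TWO_PAIRS_LABELS) == pytest.approx(0.01, abs=1e-12)

    def test_translation_invariance(self, rng):
        pts = rng.normal(size=(24, 2))
        lab = rng.integers(0, 3, size=24)
        assert davies_bouldin(pts + 1e3, lab) == pytest.approx(
            davies_bouldin(pts, lab), abs=1e-8
        )

    def test_matches_brute_force_and_sklearn_on_random_instances(self, rng):
        for _ in range(50):
            n, k = int(rng.integers(8, 30)), int(rng.integers(2, 5))
            pts = rng.normal(size=(n, 2))
            lab = rng.integers(0, k, size=n)
            if len(np.unique(lab)) < 2:
                continue
            ours = davies_bouldin(pts, lab)
            assert ours == pytest.approx(brute_dbi(pts, lab), abs=1e-9)
            assert ours == pytest.approx(skmetrics.davies_bouldin_score(pts, lab), abs=1e-9)

    def test_coincident_centroids_propagate_infinity(self):
        # two clusters centered on the same point
        pts = np.array([[-1.0], [1.0], [-2.0], [2.0]])
        assert davies_bouldin(pts, [0, 0, 1, 1]) == np.inf


class TestKmeans:
    def test_two_far_blobs_are_recovered_exactly(self):
        res = kmeans_cluster(TWO_PAIRS, 2, seed=0)
        assert adjusted_rand_score(TWO_PAIRS_LABELS, res.labels) == 1.0

    def test_k_equals_n_gives_zero_within_cluster_ss(self, rng):
        pts = rng.normal(size=(8, 2))
        res = kmeans_cluster(pts, 8, seed=0)
        assert len(np.unique(res.labels)) == 8
        wcss = sum(
            np.sum((pts[res.labels == c] - pts[res.labels == c].mean(axis=0)) ** 2)
            for c in range(8)
        )
        assert wcss == pytest.approx(0.0, abs=1e-12)

    def test_objective_beats_random_assignments(self, rng):
        pts = rng.normal(size=(40, 2))
        res = kmeans_cluster(pts, 3, seed=1)

        def wcss(labels):
            return sum(
                np.sum((pts[labels == c] - pts[labels == c].mean(axis=0)) ** 2)
                for c in np.unique(labels)
            )

        ours = wcss(res.labels)
        for _ in range(50):
            rand = rng.integers(0, 3, size=40)
            assert ours <= wcss(rand) + 1e-9

    def test_k_out_of_range_raises(self, rng):
        pts = rng.normal(size=(5, 2))
        with pytest.raises(ConfigurationError):
            kmeans_cluster(pts, 6, seed=0)
        with pytest.raises(ConfigurationError):
            kmeans_cluster(pts, 1, seed=0)

    def test_deterministic_for_fixed_seed(self, rng):
        pts = rng.normal(size=(30, 2))
        r1 = kmeans_cluster(pts, 3, seed=7)
        r2 = kmeans_cluster(pts, 3, seed=7)
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.silhouette == r2.silhouette


def blobs(rng, centers, n_per=20, sd=0.05):
    pts = np.vstack([rng.normal(c, sd, size=(n_per, len(c))) for c in centers])
    return pts


class TestSelectK:
    def test_recovers_two_blobs(self, rng):
        pts = blobs(rng, [(0, 0), (5, 5)])
        best_k, table = select_k(pts, seed=0)
        assert best_k == 2
        assert len(table) == 7  # k in 2..8

    def test_recovers_three_blobs(self, rng):
        pts = blobs(rng, [(0, 0), (5, 5), (0, 5)])
        best_k, _ = select_k(pts, seed=0)
        assert best_k == 3

    def test_table_covers_requested_range(self, rng):
        pts = rng.normal(size=(30, 2))
        _, table = select_k(pts, k_min=2, k_max=5, seed=0)
        assert table["k"].tolist() == [2, 3, 4, 5]

    def test_k_max_above_n_raises(self, rng):
        with pytest.raises(ConfigurationError):
            select_k(rng.normal(size=(5, 2)), k_min=2, k_max=6, seed=0)


@pytest.fixture(scope="module")
def easy():
    from deepsubtype.io_prep import preprocess_blocks
    from deepsubtype.simdata import simulate_multiomics

    from conftest import small_sim_config

    cfg = small_sim_config(seed=0, effect_size=8.0, noise_sd=0.3, n_samples=60)
    data, truth = simulate_multiomics(cfg)
    ds, _ = preprocess_blocks(data.blocks, data.clinical)
    return ds, truth.labels.loc[ds.sample_ids]


class TestCompareMethods:
    def test_one_row_per_method_in_requested_order(self, easy):
        ds, truth = easy
        table = compare_methods(ds, ["kmeans", "pca-kmeans"], seed=0,
                                dae_config=tiny_dae_config())
        assert table["method"].tolist() == ["kmeans", "pca-kmeans"]

    def test_all_methods_solve_well_separated_data(self, easy):
        ds, truth = easy
        table = compare_methods(ds, DEFAULT_METHODS, seed=0,
                                dae_config=tiny_dae_config(epochs=60),
                                true_labels=truth.to_numpy())
        assert set(table["method"]) == set(DEFAULT_METHODS)
        assert (table["ari"] == 1.0).all()

    def test_unknown_method_raises(self, easy):
        ds, _ = easy
        with pytest.raises(ConfigurationError, match="spectral"):
            compare_methods(ds, ["spectral"], seed=0, dae_config=tiny_dae_config())
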