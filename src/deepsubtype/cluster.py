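"""K-means clustering of embeddings and internal cluster-validity indices.

Model selection scans k over a range (default 2..8) and keeps the k with
the highest mean silhouette width. The silhouette and Davies-Bouldin
indices are computed on whatever representation was clustered — for the
autoencoder routes that is the bottleneck embedding, for raw k-means the
original feature matrix.

Conventions for degenerate cases: a point in a singleton cluster has
silhouette 0; a point with a == b == 0 (all-coincident data) scores 0; a
Davies-Bouldin pair with coincident centroids contributes +inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import adjusted_rand_score

from . import reduce as _reduce
from .exceptions import ConfigurationError, UndefinedMetricError
from .io_prep import MultiOmicsDataset
from .reduce import DaeConfig, Embedding

__all__ = [
    "ClusterResult",
    "kmeans_cluster",
    "silhouette_score",
    "davies_bouldin",
    "select_k",
    "compare_methods",
    "DEFAULT_METHODS",
]


@dataclass
class ClusterResult:
    """Labels plus the internal validity metrics of one clustering run."""

    labels: np.ndarray
    k: int
    silhouette: float
    dbi: float
    method_name: str = "kmeans"
    seed: int = 0
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        counts = np.bincount(self.labels, minlength=self.k)
        if (counts[: self.k] == 0).any():
            raise ConfigurationError("every cluster must be non-empty")

    def to_frame(self) -> pd.DataFrame:
        ids = self.sample_ids or [str(i) for i in range(len(self.labels))]
        return pd.DataFrame({"cluster": self.labels}, index=ids)


def _points_labels(points, labels) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    lab = np.asarray(labels)
    if len(lab) != pts.shape[0]:
        raise ConfigurationError("labels length must match point count")
    return pts, lab


def silhouette_score(points, labels) -> float:
    """Mean silhouette width s = (b - a) / max(a, b) over all points.

    a is the mean distance to other members of the point's own cluster and
    b the smallest mean distance to any other cluster. Singleton-cluster
    points contribute 0, as does the 0/0 case.
    """
    pts, lab = _points_labels(points, labels)
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise UndefinedMetricError("silhouette needs at least 2 clusters")
    dist = cdist(pts, pts)
    n = len(lab)
    scores = np.zeros(n)
    members = {c: np.flatnonzero(lab == c) for c in uniq}
    for i in range(n):
        own = members[lab[i]]
        if len(own) == 1:
            continue  # singleton: s = 0
        a = dist[i, own].sum() / (len(own) - 1)
        b = min(dist[i, members[c]].mean() for c in uniq if c != lab[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(scores.mean())


def davies_bouldin(points, labels) -> float:
    """Davies-Bouldin index: mean over clusters of the worst similarity ratio.

    For clusters i, j with mean within-cluster distance-to-centroid s and
    centroid separation M, the ratio is (s_i + s_j) / M_ij; coincident
    centroids give +inf, which propagates.
    """
    pts, lab = _points_labels(points, labels)
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise UndefinedMetricError("Davies-Bouldin needs at least 2 clusters")
    centroids = np.vstack([pts[lab == c].mean(axis=0) for c in uniq])
    scatter = np.array(
        [np.linalg.norm(pts[lab == c] - centroids[i], axis=1).mean() for i, c in enumerate(uniq)]
    )
    sep = cdist(centroids, centroids)
    kk = len(uniq)
    worst = np.empty(kk)
    for i in range(kk):
        ratios = []
        for j in range(kk):
            if j == i:
                continue
            if sep[i, j] == 0.0:
                ratios.append(np.inf)
            else:
                ratios.append((scatter[i] + scatter[j]) / sep[i, j])
        worst[i] = max(ratios)
    return float(worst.mean())


def kmeans_cluster(embedding, k: int, seed: int = 0, method_name: str = "kmeans") -> ClusterResult:
    """K-means (k-means++ init, 10 restarts) plus validity metrics.

    ``embedding`` may be an Embedding, DataFrame or array. Metrics are
    computed on the same coordinates that were clustered.
    """
    pts, sample_ids = _coords(embedding)
    n = pts.shape[0]
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > n:
        raise ConfigurationError(f"k={k} exceeds n_samples={n}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(pts)
    # relabel to 0..k-1 in case of (rare) empty clusters after convergence
    uniq = np.unique(labels)
    if len(uniq) < k:
        raise ConfigurationError(f"k-means converged with empty cluster(s) at k={k}")
    sil = silhouette_score(pts, labels)
    dbi = davies_bouldin(pts, labels)
    return ClusterResult(
        labels=labels,
        k=k,
        silhouette=sil,
        dbi=dbi,
        method_name=method_name,
        seed=seed,
        sample_ids=sample_ids,
    )


def _coords(embedding) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(embedding, Embedding):
        return embedding.coordinates, embedding.sample_ids
    if isinstance(embedding, pd.DataFrame):
        return embedding.to_numpy(dtype=float), [str(s) for s in embedding.index]
    arr = np.asarray(embedding, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, None


def select_k(
    embedding, k_min: int = 2, k_max: int = 8, seed: int = 0
) -> tuple[int, pd.DataFrame]:
    """Scan k in [k_min, k_max] and pick the silhouette-maximizing k.

    Returns the chosen k and the per-k metrics table; ties go to the
    smallest k.
    """
    pts, _ = _coords(embedding)
    if k_max > pts.shape[0]:
        raise ConfigurationError(f"k_max={k_max} exceeds n_samples={pts.shape[0]}")
    if k_min < 2 or k_min > k_max:
        raise ConfigurationError("need 2 <= k_min <= k_max")
    rows = []
    best_k, best_sil = None, -np.inf
    for k in range(k_min, k_max + 1):
        res = kmeans_cluster(embedding, k, seed=seed)
        rows.append({"k": k, "silhouette": res.silhouette, "dbi": res.dbi})
        if res.silhouette > best_sil:
            best_k, best_sil = k, res.silhouette
    return int(best_k), pd.DataFrame(rows)


DEFAULT_METHODS = (
    "kmeans",
    "hierarchical",
    "pca-kmeans",
    "kpca-kmeans",
    "ae-kmeans",
    "dae-kmeans",
)


def compare_methods(
    dataset: MultiOmicsDataset,
    methods=DEFAULT_METHODS,
    k: int = 2,
    seed: int = 0,
    dae_config: DaeConfig | None = None,
    true_labels=None,
) -> pd.DataFrame:
    """Cluster the cohort with several methods and tabulate their metrics.

    Raw k-means and hierarchical clustering (agglomerative, average linkage)
    run on the concatenated features; the PCA/KPCA/AE/DAE routes first embed
    to the autoencoder bottleneck dimension, then run k-means. Metrics are
    computed on the clustered representation; adjusted Rand index against
    ``true_labels`` is added when provided.
    """
    cfg = dae_config or DaeConfig(seed=seed)
    X = dataset.X
    rows = []
    for method in methods:
        if method == "kmeans":
            res = kmeans_cluster(X, k, seed=seed, method_name=method)
        elif method == "hierarchical":
            pts = X.to_numpy(dtype=float)
            labels = AgglomerativeClustering(n_clusters=k, linkage="average").fit_predict(pts)
            res = ClusterResult(
                labels=labels,
                k=k,
                silhouette=silhouette_score(pts, labels),
                dbi=davies_bouldin(pts, labels),
                method_name=method,
                seed=seed,
                sample_ids=[str(s) for s in X.index],
            )
        elif method == "pca-kmeans":
            emb = _reduce.pca_reduce(dataset, cfg.bottleneck)
            res = kmeans_cluster(emb, k, seed=seed, method_name=method)
        elif method == "kpca-kmeans":
            emb = _reduce.kpca_reduce(dataset, cfg.bottleneck, kernel="rbf")
            res = kmeans_cluster(emb, k, seed=seed, method_name=method)
        elif method == "ae-kmeans":
            model = _reduce.fit_ae(dataset, cfg)
            res = kmeans_cluster(_reduce.embed(model, dataset), k, seed=seed, method_name=method)
        elif method == "dae-kmeans":
            model = _reduce.fit_dae(dataset, cfg)
            res = kmeans_cluster(_reduce.embed(model, dataset), k, seed=seed, method_name=method)
        else:
            raise ConfigurationError(f"unknown clustering method {method!r}")
        row = {
            "method": method,
            "silhouette": res.silhouette,
            "dbi": res.dbi,
        }
        if true_labels is not None:
            row["ari"] = adjusted_rand_score(np.asarray(true_labels), res.labels)
        rows.append(row)
    return pd.DataFrame(rows)
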