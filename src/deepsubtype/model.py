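"""High-level modelling interface: fit the whole subtyping framework at once.

`MultiOmicsSubtyper` is constructed from a :class:`MultiOmicsDataset` (or
from per-block files) and `fit()` runs the framework end to end — denoising
autoencoder, bottleneck embedding, silhouette-based choice of k, k-means,
risk-group naming, log-rank test — returning a `SubtypeResults` object that
carries the estimates and a `summary()` table. The sparse mRNA classifier
hangs off the results via `fit_classifier()`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import classify as _classify
from . import cluster as _cluster
from . import io_prep as _io
from . import reduce as _reduce
from . import survival as _survival
from .exceptions import ConfigurationError
from .io_prep import MultiOmicsDataset
from .reduce import DaeConfig

__all__ = ["MultiOmicsSubtyper", "SubtypeResults"]


class MultiOmicsSubtyper:
    """Denoising-autoencoder + k-means molecular subtyping model.

    Parameters
    ----------
    dataset
        Preprocessed (fully observed, [-1, 1]-scaled) multi-omics cohort.
    dae_config
        Autoencoder hyperparameters; defaults to the 200-50-2-50-200 tanh
        network trained 100 epochs with Adam (lr 0.001, batch 256) under
        masking corruption at rate 0.2.
    k_range
        Inclusive range of cluster numbers scanned by silhouette.
    """

    def __init__(
        self,
        dataset: MultiOmicsDataset,
        dae_config: DaeConfig | None = None,
        k_range: tuple[int, int] = (2, 8),
    ):
        self.dataset = dataset
        self.dae_config = dae_config or DaeConfig()
        self.k_range = k_range

    @classmethod
    def from_files(
        cls,
        block_paths: dict[str, str],
        clinical_path: str,
        missing_threshold: float = 0.2,
        orientation: str = "samples",
        **kwargs,
    ) -> "MultiOmicsSubtyper":
        """Read raw per-block matrices + clinical table and preprocess them
        (missingness filter, median imputation, [-1, 1] scaling, alignment)."""
        blocks = [
            _io.read_matrix(path, name=name, orientation=orientation)
            for name, path in block_paths.items()
        ]
        clinical = _io.read_clinical(clinical_path)
        dataset, scalers = _io.preprocess_blocks(blocks, clinical, missing_threshold)
        model = cls(dataset, **kwargs)
        model.scalers_ = scalers
        return model

    def fit(self, seed: int | None = None) -> "SubtypeResults":
        """Train the DAE, embed, select k by silhouette, cluster, and (when
        k = 2) name risk groups and run the log-rank test."""
        cfg = self.dae_config if seed is None else replace(self.dae_config, seed=seed)
        kseed = cfg.seed
        emb_model = _reduce.fit_dae(self.dataset, cfg)
        embedding = _reduce.embed(emb_model, self.dataset)
        k_min, k_max = self.k_range
        best_k, k_table = _cluster.select_k(embedding, k_min, k_max, seed=kseed)
        clusters = _cluster.kmeans_cluster(embedding, best_k, seed=kseed, method_name="dae-kmeans")
        risk = logrank = None
        if best_k == 2:
            labels = pd.Series(clusters.labels, index=self.dataset.sample_ids)
            risk = _survival.assign_risk_groups(labels, self.dataset.clinical)
            logrank = _survival.logrank_test(
                self.dataset.clinical["time"].to_numpy(),
                self.dataset.clinical["event"].to_numpy(),
                risk.risk.to_numpy(),
            )
        return SubtypeResults(
            model=self,
            embedding_model=emb_model,
            embedding=embedding,
            k_table=k_table,
            clusters=clusters,
            risk_groups=risk,
            logrank=logrank,
        )


@dataclass
class SubtypeResults:
    """Fitted subtyping framework: embedding, clusters, survival split."""

    model: MultiOmicsSubtyper
    embedding_model: _reduce.EmbeddingModel
    embedding: _reduce.Embedding
    k_table: pd.DataFrame
    clusters: _cluster.ClusterResult
    risk_groups: _survival.RiskGroups | None
    logrank: _survival.LogrankResult | None

    @property
    def k(self) -> int:
        return self.clusters.k

    @property
    def labels(self) -> pd.Series:
        return pd.Series(self.clusters.labels, index=self.model.dataset.sample_ids, name="cluster")

    def fit_classifier(
        self,
        block: str = "mRNA",
        lambda_grid=(0.01, 0.1, 1.0, 10.0),
        folds: int = 5,
        seed: int = 0,
    ) -> _classify.SparseLogisticModel:
        """Train the sparse logistic signature on one block (default mRNA)
        against the fitted risk labels, choosing lambda by stratified CV."""
        if self.risk_groups is None:
            raise ConfigurationError("classifier requires a 2-cluster fit with risk groups")
        X = self.model.dataset.block(block).data
        y = self.risk_groups.risk.loc[X.index].to_numpy()
        lam = _classify.select_lambda(X, y, lambda_grid, folds=folds, seed=seed)
        return _classify.fit_l1_logistic(X, y, lam)

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "Multi-omics DAE-kmeans subtyping results",
            "=" * 46,
            f"samples: {ds.n_samples}",
            "blocks: "
            + ", ".join(f"{b.name} ({b.n_features} features)" for b in ds.blocks),
            f"bottleneck dimension: {self.model.dae_config.bottleneck}",
            f"final training loss: {self.embedding_model.loss_history[-1]:.4f} "
            f"(epoch 1: {self.embedding_model.loss_history[0]:.4f})",
            f"selected k: {self.k} (silhouette-maximizing over "
            f"[{self.model.k_range[0]}, {self.model.k_range[1]}])",
            f"silhouette: {self.clusters.silhouette:.4f}",
            f"Davies-Bouldin index: {self.clusters.dbi:.4f}",
        ]
        counts = np.bincount(self.clusters.labels, minlength=self.k)
        lines.append(
            "cluster sizes: " + ", ".join(f"{c}: {n}" for c, n in enumerate(counts[: self.k]))
        )
        if self.risk_groups is not None and self.logrank is not None:
            rg = self.risk_groups
            n_high = int((rg.risk == _survival.HIGH_RISK).sum())
            n_low = int((rg.risk == _survival.LOW_RISK).sum())
            lines += [
                f"risk groups: Low = {n_low}, High = {n_high} "
                f"(cluster→risk map: {rg.mapping})",
                f"log-rank: chi2(1) = {self.logrank.statistic:.3f}, "
                f"p = {self.logrank.p_value:.3g}",
            ]
        return "\n".join(lines)
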