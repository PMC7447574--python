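"""Dimensionality reduction of the concatenated multi-omics matrix.

The centrepiece is a denoising autoencoder (DAE): a symmetric 7-layer
multilayer perceptron (input, five hidden layers of 200-50-2-50-200 units by
default, output) with tanh activations on every layer, trained with Adam to
reconstruct the *clean* input x from a stochastically corrupted version
x~ = q(x~|x).  The 2-unit bottleneck z = f_e(x) is the low-dimensional
representation handed to clustering.  With corruption rate 0 the objective
degenerates exactly to the plain autoencoder reconstruction loss
||x - f_d(f_e(x))||_2^2, and fit_ae is implemented that way, so the two
training paths are identical by construction at rate 0.

The network is implemented directly on numpy: the models involved are tiny
(a few hundred units), and a pure-numpy implementation is bit-for-bit
reproducible under a fixed seed in single-threaded execution.

PCA and kernel-PCA baselines (via scikit-learn) share the Embedding return
type so clustering can consume any of them interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA, KernelPCA

from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    DimensionError,
    TrainingDivergenceError,
)
from .io_prep import MultiOmicsDataset

__all__ = [
    "DaeConfig",
    "EmbeddingModel",
    "Embedding",
    "corrupt",
    "reconstruction_loss",
    "fit_dae",
    "fit_ae",
    "embed",
    "pca_reduce",
    "kpca_reduce",
]


@dataclass(frozen=True)
class DaeConfig:
    """Hyperparameters of the (denoising) autoencoder.

    Defaults: hidden layers 200-50-2-50-200 (bottleneck 2), tanh activation
    throughout, Adam with learning rate 0.001, batch size 256, 100 epochs,
    masking corruption at rate 0.2.
    """

    hidden_sizes: tuple[int, ...] = (200, 50, 2, 50, 200)
    learning_rate: float = 0.001
    batch_size: int = 256
    epochs: int = 100
    corruption_rate: float = 0.2
    corruption_kind: str = "masking"
    seed: int = 0

    def __post_init__(self) -> None:
        hs = tuple(self.hidden_sizes)
        if len(hs) % 2 == 0 or hs != hs[::-1]:
            raise ConfigurationError(
                f"hidden_sizes must be palindromic with odd length, got {hs}"
            )
        if any(h < 1 for h in hs):
            raise ConfigurationError("hidden sizes must be positive")
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ConfigurationError("corruption_rate must be in [0, 1]")
        if self.corruption_kind not in ("masking", "gaussian"):
            raise ConfigurationError(
                f"corruption_kind must be 'masking' or 'gaussian', got "
                f"{self.corruption_kind!r}"
            )
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")

    @property
    def bottleneck(self) -> int:
        return self.hidden_sizes[len(self.hidden_sizes) // 2]


@dataclass
class Embedding:
    """Low-dimensional coordinates z, one row per sample."""

    sample_ids: list[str]
    coordinates: np.ndarray
    method: str = "dae"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[0] != len(self.sample_ids):
            raise DimensionError("coordinate rows must match sample count")

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"z{i + 1}" for i in range(self.d)]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


@dataclass
class EmbeddingModel:
    """A trained encoder/decoder pair with its training history."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_names: list[str]
    config: DaeConfig
    loss_history: list[float]

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def _encoder_depth(self) -> int:
        # layers up to and including the bottleneck
        return len(self.config.hidden_sizes) // 2 + 1

    def encode(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(x, dtype=float)
        for W, b in zip(self.weights[: self._encoder_depth], self.biases[: self._encoder_depth]):
            h = np.tanh(h @ W + b)
        return h

    def decode(self, z: np.ndarray) -> np.ndarray:
        h = np.asarray(z, dtype=float)
        for W, b in zip(self.weights[self._encoder_depth :], self.biases[self._encoder_depth :]):
            h = np.tanh(h @ W + b)
        return h

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(x))

    def save(self, path: str | Path) -> None:
        arrays = {f"W{i}": W for i, W in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(
            path,
            **arrays,
            feature_names=np.array(self.feature_names),
            loss_history=np.array(self.loss_history),
            hidden_sizes=np.array(self.config.hidden_sizes),
            scalars=np.array(
                [
                    self.config.learning_rate,
                    self.config.batch_size,
                    self.config.epochs,
                    self.config.corruption_rate,
                    self.config.seed,
                ]
            ),
            corruption_kind=np.array(self.config.corruption_kind),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        with np.load(path, allow_pickle=False) as f:
            n = len([k for k in f.files if k.startswith("W")])
            weights = [f[f"W{i}"] for i in range(n)]
            biases = [f[f"b{i}"] for i in range(n)]
            lr, bs, ep, cr, seed = f["scalars"]
            cfg = DaeConfig(
                hidden_sizes=tuple(int(h) for h in f["hidden_sizes"]),
                learning_rate=float(lr),
                batch_size=int(bs),
                epochs=int(ep),
                corruption_rate=float(cr),
                corruption_kind=str(f["corruption_kind"]),
                seed=int(seed),
            )
            return cls(
                weights=weights,
                biases=biases,
                feature_names=[str(s) for s in f["feature_names"]],
                config=cfg,
                loss_history=[float(v) for v in f["loss_history"]],
            )


def corrupt(
    x: np.ndarray,
    rate: float,
    kind: str = "masking",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Stochastically corrupt a feature matrix; the input is left untouched.

    ``masking`` zeroes each cell independently with probability ``rate``;
    ``gaussian`` adds Normal(0, rate * per-feature std) noise. Rate 0 returns
    an exact copy.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"corruption rate must be in [0, 1], got {rate}")
    if kind not in ("masking", "gaussian"):
        raise ConfigurationError(f"unknown corruption kind {kind!r}")
    x = np.asarray(x, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    if rate == 0.0:
        return x.copy()
    if kind == "masking":
        mask = rng.random(x.shape) < rate
        return np.where(mask, 0.0, x)
    scale = x.std(axis=0, ddof=0)
    return x + rng.normal(0.0, 1.0, size=x.shape) * (rate * scale)


def reconstruction_loss(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Mean over samples of the squared Euclidean reconstruction error."""
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    if x.shape != x_prime.shape:
        raise DimensionError(f"shape mismatch: {x.shape} vs {x_prime.shape}")
    return float(np.mean(np.sum((x - x_prime) ** 2, axis=1)))


def _as_matrix(data) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(data, MultiOmicsDataset):
        df = data.X
    elif isinstance(data, pd.DataFrame):
        df = data
    else:
        arr = np.asarray(data, dtype=float)
        return arr, [str(i) for i in range(arr.shape[0])], [f"x{j}" for j in range(arr.shape[1])]
    return df.to_numpy(dtype=float), [str(s) for s in df.index], [str(c) for c in df.columns]


def _init_params(
    sizes: Sequence[int], rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    # uniform fan-based (Glorot) initialization, seeded
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def fit_dae(data, config: DaeConfig | None = None) -> EmbeddingModel:
    """Train a denoising autoencoder on a preprocessed feature matrix.

    ``data`` may be a MultiOmicsDataset (its concatenated matrix is used), a
    DataFrame or an array; it must be fully observed and scaled into tanh's
    range [-1, 1]. Each batch draws fresh corruption; the loss is always
    measured against the clean input. Training is deterministic for a fixed
    config seed.
    """
    config = config or DaeConfig()
    x, sample_ids, feature_names = _as_matrix(data)
    if np.isnan(x).any():
        raise DegenerateInputError("training data contains missing values; impute first")
    n, d = x.shape
    sizes = [d, *config.hidden_sizes, d]
    rng = np.random.default_rng(config.seed)
    weights, biases = _init_params(sizes, rng)

    # Adam state
    mW = [np.zeros_like(W) for W in weights]
    vW = [np.zeros_like(W) for W in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    loss_history: list[float] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_sse = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb = x[idx]
            xt = corrupt(xb, config.corruption_rate, config.corruption_kind, rng)

            # forward
            activations = [xt]
            h = xt
            for W, b in zip(weights, biases):
                h = np.tanh(h @ W + b)
                activations.append(h)
            diff = h - xb
            batch_loss = float(np.mean(np.sum(diff**2, axis=1)))
            if not np.isfinite(batch_loss):
                raise TrainingDivergenceError(epoch)
            epoch_sse += float(np.sum(diff**2))

            # backward: d(mean_i ||x_i - y_i||^2)/dy = 2*diff/B
            grad = (2.0 / len(idx)) * diff
            t += 1
            for layer in range(len(weights) - 1, -1, -1):
                a = activations[layer + 1]
                delta = grad * (1.0 - a**2)  # tanh'
                gW = activations[layer].T @ delta
                gb = delta.sum(axis=0)
                grad = delta @ weights[layer].T
                # Adam update with bias correction
                mW[layer] = beta1 * mW[layer] + (1 - beta1) * gW
                vW[layer] = beta2 * vW[layer] + (1 - beta2) * gW**2
                mb[layer] = beta1 * mb[layer] + (1 - beta1) * gb
                vb[layer] = beta2 * vb[layer] + (1 - beta2) * gb**2
                mhW = mW[layer] / (1 - beta1**t)
                vhW = vW[layer] / (1 - beta2**t)
                mhb = mb[layer] / (1 - beta1**t)
                vhb = vb[layer] / (1 - beta2**t)
                weights[layer] -= config.learning_rate * mhW / (np.sqrt(vhW) + eps)
                biases[layer] -= config.learning_rate * mhb / (np.sqrt(vhb) + eps)
        loss_history.append(epoch_sse / n)

    return EmbeddingModel(
        weights=weights,
        biases=biases,
        feature_names=feature_names,
        config=config,
        loss_history=loss_history,
    )


def fit_ae(data, config: DaeConfig | None = None) -> EmbeddingModel:
    """Train a plain autoencoder: the corruption-free special case of the DAE."""
    config = config or DaeConfig()
    return fit_dae(data, replace(config, corruption_rate=0.0))


def embed(model: EmbeddingModel, data) -> Embedding:
    """Map samples to bottleneck coordinates z = f_e(x) on clean inputs."""
    x, sample_ids, feature_names = _as_matrix(data)
    if feature_names != model.feature_names:
        missing = sorted(set(model.feature_names) - set(feature_names))
        if missing:
            raise DimensionError(
                f"input lacks {len(missing)} training features, e.g. {missing[:5]}"
            )
        if isinstance(data, MultiOmicsDataset):
            x = data.X[model.feature_names].to_numpy(dtype=float)
        elif isinstance(data, pd.DataFrame):
            x = data[model.feature_names].to_numpy(dtype=float)
        else:
            raise DimensionError("feature order mismatch for unnamed array input")
    return Embedding(sample_ids=sample_ids, coordinates=model.encode(x), method="dae")


def pca_reduce(data, d: int) -> Embedding:
    """Top-d principal-component coordinates of the (centered) feature matrix."""
    x, sample_ids, _ = _as_matrix(data)
    if d > min(x.shape):
        raise DimensionError(f"d={d} exceeds min(n_samples, n_features)={min(x.shape)}")
    coords = PCA(n_components=d, svd_solver="full").fit_transform(x)
    return Embedding(sample_ids=sample_ids, coordinates=coords, method="pca")


def kpca_reduce(data, d: int, kernel: str = "rbf", **kernel_kwargs) -> Embedding:
    """Top-d kernel-principal coordinates (default RBF kernel)."""
    x, sample_ids, _ = _as_matrix(data)
    if d > x.shape[0]:
        raise DimensionError(f"d={d} exceeds n_samples={x.shape[0]}")
    coords = KernelPCA(n_components=d, kernel=kernel, **kernel_kwargs).fit_transform(x)
    return Embedding(sample_ids=sample_ids, coordinates=coords, method=f"kpca-{kernel}")
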