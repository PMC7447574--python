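"""Synthetic multi-omics cohorts with known subtypes and survival.

The generator emulates the statistical structure the subtyping framework
assumes: several omics blocks (e.g. mRNA / miRNA / gene-level CNV) sharing a
single two-subtype latent structure, a subset of informative features per
block whose means shift between subtypes, Gaussian measurement noise, MCAR
missingness, and subtype-dependent exponential survival with independent
exponential censoring. Every draw comes from one seeded generator, so a
fixed seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io_prep import MultiOmicsDataset, OmicsMatrix, write_clinical, write_matrix

__all__ = ["BlockSpec", "SimConfig", "SimTruth", "simulate_multiomics", "simulate_survival", "write_dataset"]


@dataclass(frozen=True)
class BlockSpec:
    """One omics block to simulate: total and informative feature counts."""

    name: str
    n_features: int
    n_informative: int


def default_blocks() -> list[BlockSpec]:
    return [
        BlockSpec("mRNA", 200, 20),
        BlockSpec("miRNA", 60, 6),
        BlockSpec("cnv", 120, 12),
    ]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults are the packaged desk-scale study condition: 300 samples in two
    equal subtypes; three blocks of 200/60/120 features with 10% of each
    informative; a mean shift of delta=3 (split +/- delta/2 by subtype) on
    informative features against unit Gaussian noise; 10% MCAR missingness;
    exponential survival with baseline hazard 0.1 and hazard ratio 3 for the
    high-risk subtype; and independent exponential censoring at rate 0.04,
    which censors roughly 20% of subjects under these hazards.
    """

    n_samples: int = 300
    blocks: list[BlockSpec] = field(default_factory=default_blocks)
    effect_size: float = 3.0
    noise_sd: float = 1.0
    missing_rate: float = 0.1
    subtype_proportion: float = 0.5
    baseline_hazard: float = 0.1
    hazard_ratio: float = 3.0
    censoring_rate: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if not self.blocks:
            raise ConfigurationError("at least one block spec required")
        for b in self.blocks:
            if b.n_informative > b.n_features:
                raise ConfigurationError(
                    f"block {b.name!r}: n_informative ({b.n_informative}) > "
                    f"n_features ({b.n_features})"
                )
            if b.n_features < 1:
                raise ConfigurationError(f"block {b.name!r}: n_features must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not 0.0 < self.subtype_proportion < 1.0:
            raise ConfigurationError("subtype_proportion must be in (0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.hazard_ratio <= 0:
            raise ConfigurationError("hazard_ratio must be > 0")
        if self.censoring_rate < 0:
            raise ConfigurationError("censoring_rate must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    labels: pd.Series  # per-sample subtype in {0, 1}
    informative_features: dict[str, list[str]]  # per block
    event_times: pd.Series
    censor_times: pd.Series


def _subtype_labels(n: int, proportion: float, rng: np.random.Generator) -> np.ndarray:
    # deterministic counts (first ceil(n*p) samples are subtype 1), then a
    # seeded shuffle — label totals are exact, positions are random
    n1 = int(np.ceil(n * proportion))
    labels = np.zeros(n, dtype=int)
    labels[:n1] = 1
    rng.shuffle(labels)
    return labels


def simulate_survival(
    labels: np.ndarray | pd.Series,
    baseline_hazard: float,
    hazard_ratio: float,
    censoring_rate: float,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw subtype-dependent exponential survival with independent censoring.

    Subjects with label 0 have event hazard ``baseline_hazard``; label 1
    multiplies it by ``hazard_ratio``. Censoring times are exponential with
    rate ``censoring_rate`` (0 disables censoring). The returned clinical
    table holds the observed time (minimum of the two) and the event
    indicator, indexed like ``labels``.
    """
    if hazard_ratio <= 0:
        raise ConfigurationError("hazard_ratio must be > 0")
    if baseline_hazard <= 0:
        raise ConfigurationError("baseline_hazard must be > 0")
    if censoring_rate < 0:
        raise ConfigurationError("censoring_rate must be >= 0")
    lab = pd.Series(labels)
    if not lab.isin([0, 1]).all():
        raise ConfigurationError("labels must be 0/1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(lab)
    hazards = baseline_hazard * hazard_ratio ** lab.to_numpy()
    event_times = rng.exponential(1.0 / hazards)
    if censoring_rate > 0:
        censor_times = rng.exponential(1.0 / censoring_rate, size=n)
    else:
        censor_times = np.full(n, np.inf)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    return pd.DataFrame(
        {
            "time": observed,
            "event": event,
            "_event_time": event_times,
            "_censor_time": censor_times,
        },
        index=lab.index,
    )


def simulate_multiomics(config: SimConfig) -> tuple[MultiOmicsDataset, SimTruth]:
    """Generate a seeded multi-omics cohort with known subtype structure.

    In each block the first ``n_informative`` features are shifted by
    +effect_size/2 for subtype 1 and -effect_size/2 for subtype 0 around a
    zero grand mean; the remaining features are pure noise. All features
    carry Gaussian noise with ``noise_sd``; MCAR missingness is applied
    cell-wise at ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    labels = _subtype_labels(n, config.subtype_proportion, rng)
    signs = np.where(labels == 1, 0.5, -0.5) * config.effect_size

    blocks: list[OmicsMatrix] = []
    informative: dict[str, list[str]] = {}
    for spec in config.blocks:
        feats = [f"{spec.name}_f{j:04d}" for j in range(spec.n_features)]
        means = np.zeros((n, spec.n_features))
        means[:, : spec.n_informative] = signs[:, None]
        values = rng.normal(means, config.noise_sd)
        if config.missing_rate > 0:
            mask = rng.random(values.shape) < config.missing_rate
            values = np.where(mask, np.nan, values)
        blocks.append(
            OmicsMatrix(
                name=spec.name,
                data=pd.DataFrame(values, index=sample_ids, columns=feats),
            )
        )
        informative[spec.name] = feats[: spec.n_informative]

    surv = simulate_survival(
        pd.Series(labels, index=sample_ids),
        config.baseline_hazard,
        config.hazard_ratio,
        config.censoring_rate,
        seed=rng,
    )
    clinical = surv[["time", "event"]]
    dataset = MultiOmicsDataset(blocks=blocks, clinical=clinical)
    truth = SimTruth(
        labels=pd.Series(labels, index=sample_ids, name="true_label"),
        informative_features=informative,
        event_times=surv["_event_time"].rename("event_time"),
        censor_times=surv["_censor_time"].rename("censor_time"),
    )
    return dataset, truth


def write_dataset(dataset: MultiOmicsDataset, truth: SimTruth | None, outdir: str | Path) -> dict[str, str]:
    """Write blocks, clinical table and (optionally) the truth sidecar as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for b in dataset.blocks:
        p = outdir / f"{b.name}.csv"
        write_matrix(b, p)
        paths[b.name] = str(p)
    p = outdir / "clinical.csv"
    write_clinical(dataset.clinical, p)
    paths["clinical"] = str(p)
    if truth is not None:
        p = outdir / "truth.csv"
        truth.labels.rename("true_label").to_csv(p, index_label="sample_id")
        paths["truth"] = str(p)
    return paths
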