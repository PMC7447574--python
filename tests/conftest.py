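import numpy as np
import pandas as pd
import pytest

from deepsubtype import BlockSpec, SimConfig, simulate_multiomics
from deepsubtype.io_prep import OmicsMatrix, preprocess_blocks
from deepsubtype.reduce import DaeConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A fast, well-separated cohort for unit tests (not the study condition)."""
    defaults = dict(
        n_samples=80,
        blocks=[BlockSpec("mRNA", 30, 6), BlockSpec("miRNA", 10, 2)],
        effect_size=4.0,
        noise_sd=1.0,
        missing_rate=0.0,
        hazard_ratio=4.0,
        censoring_rate=0.02,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def tiny_dae_config(seed: int = 0, **overrides) -> DaeConfig:
    defaults = dict(hidden_sizes=(16, 2, 16), epochs=30, batch_size=64, seed=seed)
    defaults.update(overrides)
    return DaeConfig(**defaults)


@pytest.fixture
def small_cohort():
    """Preprocessed small cohort plus aligned true labels."""
    data, truth = simulate_multiomics(small_sim_config())
    dataset, _ = preprocess_blocks(data.blocks, data.clinical)
    return dataset, truth.labels.loc[dataset.sample_ids]


def random_omics(rng, n=12, p=7, missing=0.0, name="omics") -> OmicsMatrix:
    vals = rng.normal(size=(n, p))
    if missing > 0:
        mask = rng.random(vals.shape) < missing
        vals = np.where(mask, np.nan, vals)
    return OmicsMatrix(
        name=name,
        data=pd.DataFrame(
            vals,
            index=[f"S{i}" for i in range(n)],
            columns=[f"f{j}" for j in range(p)],
        ),
    )
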