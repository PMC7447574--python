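import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from deepsubtype import BlockSpec, SimConfig, simulate_multiomics
from deepsubtype.exceptions import ConfigurationError, DimensionError
from deepsubtype.io_prep import preprocess_blocks
from deepsubtype.reduce import (
    DaeConfig,
    EmbeddingModel,
    corrupt,
    embed,
    fit_ae,
    fit_dae,
    kpca_reduce,
    pca_reduce,
    reconstruction_loss,
)

from conftest import tiny_dae_config


class TestCorrupt:
    def test_rate_zero_is_identity_and_pure(self, rng):
        x = rng.normal(size=(5, 4))
        orig = x.copy()
        out = corrupt(x, 0.0, "masking", rng)
        assert np.array_equal(out, orig)
        assert out is not x

    def test_rate_one_masking_zeroes_everything(self, rng):
        x = rng.normal(size=(5, 4)) + 10
        assert (corrupt(x, 1.0, "masking", rng) == 0.0).all()

    def test_masked_fraction_within_binomial_ci(self, rng):
        x = np.ones((100, 100))
        out = corrupt(x, 0.5, "masking", rng)
        frac = (out == 0.0).mean()
        half = 3.29 * np.sqrt(0.25 / 10_000)  # 99.9% binomial CI
        assert abs(frac - 0.5) < half

    def test_gaussian_noise_scales_with_feature_spread(self, rng):
        x = np.hstack([rng.normal(0, 1, (2000, 1)), rng.normal(0, 5, (2000, 1))])
        out = corrupt(x, 0.5, "gaussian", rng)
        noise_sd = (out - x).std(axis=0)
        assert noise_sd[0] == pytest.approx(0.5 * 1, rel=0.15)
        assert noise_sd[1] == pytest.approx(0.5 * 5, rel=0.15)

    def test_unknown_kind_and_bad_rate_raise(self, rng):
        with pytest.raises(ConfigurationError):
            corrupt(np.ones((2, 2)), 0.5, "saltpepper", rng)
        with pytest.raises(ConfigurationError):
            corrupt(np.ones((2, 2)), 1.5, "masking", rng)


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self, rng):
        x = rng.normal(size=(6, 3))
        assert reconstruction_loss(x, x) == 0.0

    def test_single_sample_squared_norm(self):
        assert reconstruction_loss([[1.0, 2.0]], [[0.0, 0.0]]) == pytest.approx(5.0)

    def test_matches_elementwise_brute_force(self, rng):
        x, xp = rng.normal(size=(30, 7)), rng.normal(size=(30, 7))
        brute = sum(
            sum((x[i, j] - xp[i, j]) ** 2 for j in range(7)) for i in range(30)
        ) / 30
        assert reconstruction_loss(x, xp) == pytest.approx(brute, abs=1e-9)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(DimensionError):
            reconstruction_loss(rng.normal(size=(3, 2)), rng.normal(size=(2, 3)))


class TestDaeConfig:
    @pytest.mark.parametrize("sizes", [(200, 50, 50, 200), (10, 5, 8, 5, 11), (8, -1, 8)])
    def test_non_palindromic_or_invalid_hidden_sizes_raise(self, sizes):
        with pytest.raises(ConfigurationError):
            DaeConfig(hidden_sizes=sizes)

    def test_default_bottleneck_is_two(self):
        assert DaeConfig().bottleneck == 2


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(0)
    x = np.tanh(rng.normal(size=(60, 12)))
    return pd.DataFrame(x, index=[f"S{i}" for i in range(60)],
                        columns=[f"f{j}" for j in range(12)])


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(1)
    x = pd.DataFrame(np.tanh(rng.normal(size=(40, 10))),
                     index=[f"S{i}" for i in range(40)],
                     columns=[f"f{j}" for j in range(10)])
    return x, fit_dae(x, tiny_dae_config(epochs=10))


class TestAutoencoderTraining:
    def test_loss_decreases_over_training(self, toy):
        model = fit_dae(toy, tiny_dae_config(epochs=40))
        assert model.loss_history[-1] < model.loss_history[0]

    def test_training_is_bit_reproducible_for_fixed_seed(self, toy):
        m1 = fit_dae(toy, tiny_dae_config(seed=5))
        m2 = fit_dae(toy, tiny_dae_config(seed=5))
        assert m1.loss_history == m2.loss_history
        for W1, W2 in zip(m1.weights, m2.weights):
            assert np.array_equal(W1, W2)

    def test_dae_at_zero_corruption_equals_plain_ae_exactly(self, toy):
        cfg = tiny_dae_config(seed=2, corruption_rate=0.0)
        m_dae = fit_dae(toy, cfg)
        m_ae = fit_ae(toy, tiny_dae_config(seed=2, corruption_rate=0.2))
        assert m_dae.loss_history == m_ae.loss_history
        for W1, W2 in zip(m_dae.weights, m_ae.weights):
            assert np.array_equal(W1, W2)

    def test_zero_matrix_trains_toward_zero_loss(self):
        x = pd.DataFrame(np.zeros((20, 6)), index=[f"S{i}" for i in range(20)],
                         columns=[f"f{j}" for j in range(6)])
        model = fit_ae(x, tiny_dae_config(hidden_sizes=(4, 2, 4), epochs=20))
        assert model.loss_history[-1] <= model.loss_history[0]
        assert model.loss_history[-1] < 0.1

    def test_missing_values_rejected(self, toy):
        bad = toy.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(Exception, match="missing"):
            fit_dae(bad, tiny_dae_config())


class TestEmbed:
    def test_bottleneck_width_and_determinism(self, trained):
        x, model = trained
        e1, e2 = embed(model, x), embed(model, x)
        assert e1.d == 2
        assert np.array_equal(e1.coordinates, e2.coordinates)

    def test_duplicate_rows_map_to_identical_coordinates(self, trained):
        x, model = trained
        dup = pd.concat([x.iloc[[0]].set_axis(["dup"]), x])
        e = embed(model, dup)
        assert np.array_equal(e.coordinates[0], e.coordinates[1])

    def test_feature_mismatch_lists_missing_features(self, trained):
        x, model = trained
        with pytest.raises(DimensionError, match="f9"):
            embed(model, x.drop(columns=["f9"]))

    def test_column_order_does_not_change_embedding(self, trained):
        x, model = trained
        shuffled = x[list(x.columns[::-1])]
        assert np.allclose(embed(model, x).coordinates, embed(model, shuffled).coordinates)

    def test_model_round_trips_through_npz(self, trained, tmp_path):
        x, model = trained
        p = tmp_path / "model.npz"
        model.save(p)
        back = EmbeddingModel.load(p)
        assert np.allclose(back.encode(x.to_numpy()), model.encode(x.to_numpy()))
        assert back.config == model.config


class TestSubtypeSignalRecovery:
    def test_bottleneck_separates_true_subtypes(self):
        # single block, strong effect: 2-means on z recovers truth (ARI >= 0.9)
        cfg = SimConfig(n_samples=300, blocks=[BlockSpec("mRNA", 200, 20)],
                        effect_size=3.0, noise_sd=1.0, missing_rate=0.0, seed=4)
        data, truth = simulate_multiomics(cfg)
        dataset, _ = preprocess_blocks(data.blocks, data.clinical)
        model = fit_dae(dataset, DaeConfig(seed=4))
        z = embed(model, dataset).coordinates
        labels = KMeans(n_clusters=2, n_init=10, random_state=4).fit_predict(z)
        ari = adjusted_rand_score(truth.labels.loc[dataset.sample_ids].to_numpy(), labels)
        assert ari >= 0.9


class TestLinearBaselines:
    def test_pca_on_collinear_data_reconstructs_exactly(self, rng):
        t = rng.normal(size=(50, 1))
        x = t @ np.array([[1.0, -2.0, 0.5]]) + 3.0  # points on a line in 3-D
        emb = pca_reduce(x, 1)
        # reconstruct from the single component
        centered = x - x.mean(axis=0)
        u = centered / np.linalg.norm(centered, axis=1, keepdims=True)
        recon_err = np.linalg.norm(
            centered - emb.coordinates @ (emb.coordinates.T @ centered) /
            (emb.coordinates.T @ emb.coordinates)
        )
        assert recon_err == pytest.approx(0.0, abs=1e-8)

    def test_pca_coordinates_have_diagonal_decreasing_covariance(self, rng):
        x = rng.normal(size=(40, 6)) @ np.diag([5, 3, 2, 1, 0.5, 0.1])
        emb = pca_reduce(x, 4)
        cov = np.cov(emb.coordinates.T)
        off = cov - np.diag(np.diag(cov))
        assert np.allclose(off, 0.0, atol=1e-8)
        assert (np.diff(np.diag(cov)) <= 1e-8).all()

    def test_linear_kernel_kpca_matches_pca_up_to_sign(self, rng):
        x = rng.normal(size=(30, 8))
        p = pca_reduce(x, 3).coordinates
        k = kpca_reduce(x, 3, kernel="linear").coordinates
        for j in range(3):
            r = np.corrcoef(p[:, j], k[:, j])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_excessive_dimension_raises(self, rng):
        with pytest.raises(DimensionError):
            pca_reduce(rng.normal(size=(5, 3)), 4)
        with pytest.raises(DimensionError):
            kpca_reduce(rng.normal(size=(5, 3)), 6)
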