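"""CVAE mechanics: reparameterisation, losses, gradients, training loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circuitgen.cvae import (
    CVAE,
    CVAEResults,
    ModelConfig,
    TrainConfig,
    forward,
    init_params,
    kl_elements,
    learning_rate,
    loss_and_grads,
    reparameterise,
    validation_accuracy,
)
from circuitgen.dataset import ConditionedDataset, fit_feature_normalisation


class TestReparameterisation:
    def test_zero_noise_is_deterministic(self):
        mu = np.array([[1.0, -2.0]])
        assert np.array_equal(reparameterise(mu, np.zeros((1, 2)), np.zeros((1, 2))), mu)

    def test_unit_variance_shifts_by_noise(self):
        mu = np.zeros((1, 3))
        nu = np.array([[0.5, -1.0, 2.0]])
        np.testing.assert_array_equal(reparameterise(mu, np.zeros((1, 3)), nu), mu + nu)

    def test_logvar_sets_sample_scale(self):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal((100_000, 1))
        z = reparameterise(np.zeros((100_000, 1)), np.full((100_000, 1), 2 * np.log(3.0)), noise)
        assert z.std() == pytest.approx(3.0, rel=0.02)


class TestKL:
    def test_standard_normal_has_zero_kl(self):
        assert np.all(kl_elements(np.zeros((4, 8)), np.zeros((4, 8))) == 0.0)

    def test_unit_mean_gives_half(self):
        assert kl_elements(np.array([[1.0]]), np.array([[0.0]]))[0, 0] == pytest.approx(0.5)

    @settings(deadline=None, max_examples=200)
    @given(
        st.floats(min_value=-10, max_value=10),
        st.floats(min_value=-8, max_value=8),
    )
    def test_nonnegative_everywhere(self, mu, logvar):
        assert kl_elements(np.array([[mu]]), np.array([[logvar]]))[0, 0] >= 0.0


@pytest.fixture
def tiny():
    config = ModelConfig(n_features=3, c_n=1, hidden=4, n_hidden_layers=2, latent=2)
    rng = np.random.default_rng(0)
    params = init_params(config, rng)
    x = rng.uniform(0, 1, (5, 3))
    c = rng.uniform(0, 1, (5, 1))
    noise = rng.standard_normal((5, 2))
    return config, params, x, c, noise


class TestForward:
    def test_concatenation_widths(self):
        config = ModelConfig(n_features=6, c_n=1)
        params = init_params(config, np.random.default_rng(0))
        assert params["enc0_W"].shape == (7, 32)  # [x, c] into the encoder
        assert params["dec0_W"].shape == (33, 32)  # [z, c] into the decoder
        assert params["out_W"].shape == (32, 6)

    def test_joint_objective_widens_decoder_input(self):
        config = ModelConfig(n_features=6, c_n=2)
        params = init_params(config, np.random.default_rng(0))
        assert params["dec0_W"].shape == (34, 32)

    def test_pure_function(self, tiny):
        config, params, x, c, noise = tiny
        y1, mu1, lv1 = forward(params, config, x, c, noise)
        y2, mu2, lv2 = forward(params, config, x, c, noise)
        np.testing.assert_array_equal(y1, y2)
        np.testing.assert_array_equal(mu1, mu2)

    def test_output_shape_matches_input(self, tiny):
        config, params, x, c, noise = tiny
        y, mu, logvar = forward(params, config, x, c, noise)
        assert y.shape == x.shape
        assert mu.shape == (5, config.latent) and logvar.shape == (5, config.latent)


class TestLoss:
    def test_perfect_reconstruction_zero_mse(self, tiny):
        config, params, x, c, noise = tiny
        y, mu, lv = forward(params, config, x, c, noise)
        total, comps, _ = loss_and_grads(params, config, y, c, noise, TrainConfig())
        # reconstruct y itself is not exactly y, so instead check mse formula:
        assert comps["mse"] == pytest.approx(float(np.mean(
            (forward(params, config, y, c, noise)[0] - y) ** 2)))

    def test_contrastive_vanishes_at_threshold(self, tiny):
        config, params, x, c, noise = tiny
        # labels whose pairwise dot products all equal the threshold d
        d = 0.25
        c_eq = np.full((5, 1), np.sqrt(d))
        train = TrainConfig(contrastive=True, contrastive_threshold=d)
        _, comps, _ = loss_and_grads(params, config, x, c_eq, noise, train)
        assert comps["contrastive"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("contrastive", [False, True])
    def test_gradients_match_finite_differences(self, tiny, contrastive):
        """Analytic gradients of the total loss agree with central finite
        differences within 1e-4 relative on a tiny model."""
        config, params, x, c, noise = tiny
        train = TrainConfig(contrastive=contrastive, kl_weight=1e-2)
        _, _, grads = loss_and_grads(params, config, x, c, noise, train)
        eps = 1e-6
        rng = np.random.default_rng(1)
        for name, grad in grads.items():
            flat = grad.ravel()
            # probe a few random coordinates of every parameter tensor
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                pos = np.unravel_index(idx, grad.shape)
                orig = params[name][pos]
                params[name][pos] = orig + eps
                up, _, _ = loss_and_grads(params, config, x, c, noise, train)
                params[name][pos] = orig - eps
                down, _, _ = loss_and_grads(params, config, x, c, noise, train)
                params[name][pos] = orig
                numeric = (up - down) / (2 * eps)
                assert numeric == pytest.approx(flat[idx], rel=1e-4, abs=1e-9), name


class TestSchedule:
    def test_warmup_and_peak(self):
        train = TrainConfig()
        assert learning_rate(0, train) == 0.0
        assert learning_rate(20, train) == pytest.approx(1e-3)

    def test_cosine_decays_to_zero(self):
        train = TrainConfig()
        assert learning_rate(2000, train) == pytest.approx(0.0, abs=1e-12)
        assert learning_rate(1010, train) == pytest.approx(
            1e-3 * 0.5 * (1 + np.cos(np.pi * 990 / 1980))
        )

    def test_kl_weight_band_warning(self):
        with pytest.warns(UserWarning, match="kl_weight"):
            TrainConfig(kl_weight=0.5)


def _toy_model(n=300, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, (n, 6))
    c = x.mean(axis=1, keepdims=True)
    return CVAE(x[: n - 60], c[: n - 60], x[n - 60 :], c[n - 60 :])


class TestTraining:
    def test_identical_seed_bitwise_identical_history(self):
        model = _toy_model()
        cfg = TrainConfig(max_epochs=15, seed=3)
        h1 = model.fit(cfg).history
        h2 = model.fit(cfg).history
        pd.testing.assert_frame_equal(h1, h2)

    def test_loss_decreases_on_toy_problem(self):
        model = _toy_model()
        res = model.fit(TrainConfig(max_epochs=60, seed=0))
        assert res.history["mse"].iloc[-1] < res.history["mse"].iloc[0] / 3

    def test_stopping_rules_and_accuracy(self):
        model = _toy_model(n=400)
        res = model.fit(TrainConfig(max_epochs=1500, seed=0))
        assert res.stop_reason in ("val_accuracy", "patience", "max_epochs")
        assert res.best_val_accuracy > 0.9
        if res.stop_reason == "patience":
            # stopped strictly before the epoch cap
            assert len(res.history) < 1500

    def test_validation_accuracy_modes(self):
        config = ModelConfig(n_features=2, c_n=1, hidden=2, n_hidden_layers=1, latent=1)
        params = init_params(config, np.random.default_rng(0))
        x = np.array([[0.5, 0.5]])
        c = np.array([[0.5]])
        y, _, _ = forward(params, config, x, c)
        bound_all = float(np.max(np.abs(y - x)))
        bound_mae = float(np.mean(np.abs(y - x)))
        assert validation_accuracy(params, config, x, c, bound_all + 1e-12, "all") == 1.0
        assert validation_accuracy(params, config, x, c, bound_all - 1e-12, "all") == 0.0
        assert validation_accuracy(params, config, x, c, bound_mae + 1e-12, "mae") == 1.0


class TestGenerationAndPersistence:
    def test_prompt_grid_accepted_and_tagged(self):
        model = _toy_model()
        res = model.fit(TrainConfig(max_epochs=10, seed=1))
        prompts = np.linspace(-0.2, 1.2, 10)[:, None]
        gen = res.sample(prompts, n_per_prompt=20, seed=5, denormalise=False)
        assert len(gen) == 200
        assert sorted(gen["prompt"].unique()) == pytest.approx(list(prompts.ravel()))

    def test_fixed_seed_identical_generation(self):
        res = _toy_model().fit(TrainConfig(max_epochs=5, seed=1))
        a = res.sample(np.array([[0.5]]), n_per_prompt=10, seed=9, denormalise=False)
        b = res.sample(np.array([[0.5]]), n_per_prompt=10, seed=9, denormalise=False)
        pd.testing.assert_frame_equal(a, b)

    def test_generation_denormalises_to_kcal_per_mol(self):
        rng = np.random.default_rng(0)
        energies = rng.uniform(-30, 0, (200, 6))
        state = fit_feature_normalisation(energies)
        from circuitgen.dataset import normalise_features

        x = normalise_features(energies, state)
        c = x.mean(axis=1, keepdims=True)
        model = CVAE(x, c, state=state)
        res = model.fit(TrainConfig(max_epochs=10, seed=0))
        gen = res.sample(np.array([[0.5]]), n_per_prompt=50, seed=0)
        assert set(state.feature_names) <= set(gen.columns)
        # kcal/mol output is exactly the inverse-normalised [0, 1] output
        raw = res.sample(np.array([[0.5]]), n_per_prompt=50, seed=0, denormalise=False)
        from circuitgen.dataset import denormalise_features

        expected = denormalise_features(
            raw[[f"x{i}" for i in range(6)]].to_numpy(), state
        )
        np.testing.assert_allclose(gen[state.feature_names].to_numpy(), expected)

    def test_checkpoint_roundtrip(self, tmp_path):
        res = _toy_model().fit(TrainConfig(max_epochs=8, seed=2))
        res.save(tmp_path / "model")
        back = CVAEResults.load(tmp_path / "model")
        x = np.random.default_rng(3).uniform(0, 1, (7, 6))
        c = x.mean(axis=1, keepdims=True)
        np.testing.assert_array_equal(back.reconstruct(x, c), res.reconstruct(x, c))
        assert back.config == res.config
        assert back.stop_reason == res.stop_reason

    def test_wrong_prompt_width_rejected(self):
        res = _toy_model().fit(TrainConfig(max_epochs=3, seed=0))
        with pytest.raises(ValueError, match="columns"):
            res.sample(np.zeros((2, 3)), n_per_prompt=1)
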