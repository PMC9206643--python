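"""Conditional-GAN colorizer: losses, training mechanics, inference."""

import numpy as np
import pytest

from parstain.colorizer import (
    DiscriminatorNet,
    GeneratorNet,
    ModelBundle,
    TrainConfig,
    colorize,
    discriminator_loss,
    generator_loss,
    make_training_pairs,
    train,
)
from parstain.preprocess import NormalizedStack
from parstain.tiling import plan_tiles


def _toy_pairs(rng, n=8, t=16):
    """Paired tiles with a learnable channel mapping plus noise."""
    from scipy.ndimage import gaussian_filter

    x = np.stack([
        np.stack([gaussian_filter(rng.uniform(0, 1, (t, t)), 2) for _ in range(3)])
        for _ in range(n)
    ])
    x = (x - x.min()) / (x.max() - x.min())
    y = np.clip(np.stack([x[:, 0] * 0.2 + 0.1, x[:, 1] * 0.5 + 0.2, x[:, 2]], axis=1), 0, 1)
    return x, y


class TestLossClosedForms:
    def test_perfect_discrimination_drives_loss_to_zero(self):
        loss = discriminator_loss(np.ones((4, 4)), np.zeros((4, 4)))
        assert loss < 1e-9

    def test_maximally_confused_discriminator_at_two_ln_two(self):
        loss = discriminator_loss(np.full((5, 5), 0.5), np.full((5, 5), 0.5))
        assert loss == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_discriminator_loss_permutation_invariant(self, rng):
        real = rng.uniform(0.01, 0.99, (6, 6))
        fake = rng.uniform(0.01, 0.99, (6, 6))
        shuffled = rng.permutation(real.ravel()).reshape(6, 6)
        assert discriminator_loss(real, fake) == pytest.approx(
            discriminator_loss(shuffled, fake)
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            discriminator_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_generator_loss_vanishes_for_perfect_fake(self):
        img = np.full((4, 4, 3), 0.3)
        assert generator_loss(np.ones((2, 2)), img, img, 100.0) < 1e-9

    def test_generator_loss_reduces_to_adversarial_term(self, rng):
        fake = rng.uniform(0, 1, (4, 4, 3))
        real = rng.uniform(0, 1, (4, 4, 3))
        score = np.full((2, 2), 0.7)
        assert generator_loss(score, fake, real, 0.0) == pytest.approx(
            -np.log(0.7), abs=1e-12
        )

    def test_generator_loss_worked_example(self):
        """Scores 0.5, uniform 0.1 error, lambda 100 -> ln 2 + 10."""
        real = np.full((3, 3, 3), 0.4)
        fake = real + 0.1
        loss = generator_loss(np.full((2, 2), 0.5), fake, real, 100.0)
        assert loss == pytest.approx(np.log(2) + 10.0, abs=1e-9)


class TestNetworks:
    def test_generator_output_bounded_for_wild_inputs(self, rng):
        gen = GeneratorNet(depth=2, base_width=4, rng=rng)
        x = rng.normal(0, 10, (2, 3, 16, 16))
        y = gen.forward(x)
        assert y.shape == (2, 3, 16, 16)
        assert (y >= 0).all() and (y <= 1).all()

    @pytest.mark.parametrize("size", [16, 32])
    def test_generator_preserves_spatial_shape(self, rng, size):
        gen = GeneratorNet(depth=2, base_width=4, rng=rng)
        assert gen.forward(np.zeros((1, 3, size, size))).shape == (1, 3, size, size)

    def test_discriminator_score_map_smaller_than_input(self, rng):
        disc = DiscriminatorNet(base_width=4, rng=rng)
        z = disc.forward(rng.uniform(0, 1, (2, 6, 32, 32)))
        assert z.ndim == 4 and z.shape[1] == 1
        assert z.shape[2] < 32 and z.shape[3] < 32


class TestTraining:
    def test_overfit_reduces_l1_term(self, rng):
        x, y = _toy_pairs(rng)
        cfg = TrainConfig(max_epochs=15, patience_epochs=15, batch_size=4, seed=0,
                          depth=2, base_width=4, disc_base_width=4, lr=2e-3)
        bundle = train((x, y), None, cfg)
        gen = bundle.build_generator()
        final_l1 = float(np.mean(np.abs(gen.forward(x) - y)))
        initial_l1 = float(
            np.mean(np.abs(GeneratorNet(2, 4, rng=np.random.default_rng(0)).forward(x) - y))
        )
        assert final_l1 < initial_l1
        # trailing-window improvement of the recorded generator loss
        g = bundle.history["g_loss"]
        assert np.mean(g[-3:]) < np.mean(g[:3])

    def test_seeded_determinism_identical_histories(self, rng):
        x, y = _toy_pairs(rng, n=4)
        cfg = TrainConfig(max_epochs=5, patience_epochs=5, batch_size=2, seed=7,
                          depth=2, base_width=4, disc_base_width=4)
        h1 = train((x, y), None, cfg).history
        h2 = train((x, y), None, cfg).history
        assert h1 == h2

    def test_zero_patience_stops_at_first_non_improving_epoch(self, rng):
        x, y = _toy_pairs(rng, n=4)
        cfg = TrainConfig(max_epochs=60, patience_epochs=0, min_delta=1e-4,
                          batch_size=2, seed=1, depth=2, base_width=4,
                          disc_base_width=4)
        bundle = train((x, y), (x[:2], y[:2]), cfg)
        val = bundle.history["val_g_loss"]
        assert len(val) < 60
        best = np.inf
        for epoch_loss in val[:-1]:  # every epoch but the last improved
            assert epoch_loss < best - cfg.min_delta
            best = epoch_loss
        assert val[-1] >= best - cfg.min_delta

    def test_history_invariants_and_best_epoch(self, rng):
        x, y = _toy_pairs(rng, n=4)
        cfg = TrainConfig(max_epochs=8, patience_epochs=2, batch_size=2, seed=2,
                          depth=2, base_width=4, disc_base_width=4)
        bundle = train((x, y), None, cfg)
        n = len(bundle.history["g_loss"])
        assert 1 <= n <= cfg.max_epochs
        assert 0 <= bundle.best_epoch <= n - 1

    def test_empty_training_set_rejected(self):
        cfg = TrainConfig(max_epochs=1)
        with pytest.raises(ValueError):
            train((np.zeros((0, 3, 8, 8)), np.zeros((0, 3, 8, 8))), None, cfg)


class TestBundleAndInference:
    def test_bundle_round_trips_bit_exactly(self, tmp_path, rng):
        x, y = _toy_pairs(rng, n=4)
        cfg = TrainConfig(max_epochs=2, patience_epochs=2, batch_size=2, seed=3,
                          depth=2, base_width=4, disc_base_width=4)
        bundle = train((x, y), None, cfg, provenance=["prep"])
        bundle.save(tmp_path / "bundle")
        back = ModelBundle.load(tmp_path / "bundle")
        for a, b in zip(bundle.gen_params, back.gen_params):
            for k in a:
                assert np.array_equal(a[k], b[k])
        assert back.config == cfg
        assert back.provenance == ["prep"]
        assert back.history["g_loss"] == pytest.approx(bundle.history["g_loss"])

    def test_colorize_shape_and_determinism(self, rng):
        cfg = TrainConfig(max_epochs=1, depth=2, base_width=4, disc_base_width=4, seed=4)
        gen_rng = np.random.default_rng(4)
        gen = GeneratorNet(2, 4, rng=gen_rng)
        bundle = ModelBundle(
            gen_params=[{k: v.copy() for k, v in l.params.items()} for l in gen.param_layers()],
            disc_params=[{k: v.copy() for k, v in l.params.items()}
                         for l in DiscriminatorNet(4, rng=gen_rng).param_layers()],
            config=cfg,
        )
        stack = NormalizedStack(rng.uniform(0, 1, (3, 48, 40)), provenance=["p"])
        grid = plan_tiles((48, 40), 16, 0.5)
        out1 = colorize(bundle, stack, grid)
        out2 = colorize(bundle, stack, grid)
        assert out1.rgb.shape == (48, 40, 3)
        assert out1.rgb.min() >= 0 and out1.rgb.max() <= 1
        assert np.array_equal(out1.rgb, out2.rgb)

    def test_colorize_warns_on_provenance_mismatch(self, rng):
        cfg = TrainConfig(max_epochs=1, depth=2, base_width=4, disc_base_width=4)
        gen = GeneratorNet(2, 4, rng=np.random.default_rng(0))
        bundle = ModelBundle(
            gen_params=[{k: v.copy() for k, v in l.params.items()} for l in gen.param_layers()],
            disc_params=[],
            config=cfg,
            provenance=["trained-with-this"],
        )
        stack = NormalizedStack(rng.uniform(0, 1, (3, 16, 16)), provenance=["other"])
        grid = plan_tiles((16, 16), 16, 0.5)
        with pytest.warns(UserWarning, match="provenance"):
            colorize(bundle, stack, grid)

    def test_make_training_pairs_layout(self, clean_phantom):
        from parstain.preprocess import prepare_input

        norm = prepare_input(clean_phantom.contrast)
        grid = plan_tiles(norm.shape, 32, 0.0)
        x, y = make_training_pairs(norm, clean_phantom.he_true, grid)
        assert x.shape == y.shape == (16, 3, 32, 32)
        assert np.array_equal(x[0, 0], norm.channels[0][:32, :32])
        assert np.array_equal(y[0, :, :, :].transpose(1, 2, 0),
                              clean_phantom.he_true.rgb[:32, :32])
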