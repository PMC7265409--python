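"""Translation network: multiscale inputs, losses, gradients, smoke training."""

import numpy as np
import pytest

from bf2holo.gan import (
    Checkpoint,
    Discriminator,
    DiscriminatorSpec,
    GeneratorSpec,
    MultiscaleGenerator,
    TrainConfig,
    build_multiscale_inputs,
    discriminator_loss,
    generator_loss,
    train,
    translate,
)
from bf2holo.metrics import bce, mse_rms


class TestMultiscaleInputs:
    def test_scale_chain_for_256(self):
        scales = build_multiscale_inputs(np.zeros((256, 256)))
        assert [s.shape for s in scales] == [(256, 256), (128, 128), (64, 64), (16, 16)]

    def test_constant_image_stays_constant_at_all_scales(self):
        scales = build_multiscale_inputs(np.full((64, 64), 0.37))
        for s in scales:
            np.testing.assert_allclose(s, 0.37)

    def test_indivisible_shape_padded_with_warning(self):
        with pytest.warns(UserWarning, match="not divisible"):
            scales = build_multiscale_inputs(np.zeros((100, 100)))
        assert scales[0].shape == (112, 112)

    def test_downscale_preserves_mean_and_centroid(self):
        """Anti-aliased area downsampling keeps intensity and feature position.

        Resampling oracle: the mean must match the input mean, and the
        centroid of a sub-coarse-pixel blob must survive every scale to well
        under one coarse pixel (position information the translation network
        depends on).
        """
        image = np.zeros((128, 128))
        image[60:68, 80:88] = 1.0  # centroid at (63.5, 83.5)
        scales = build_multiscale_inputs(image)
        for s, f in zip(scales, (1, 2, 4, 16)):
            assert s.mean() == pytest.approx(image.mean(), rel=0.05)
            yy, xx = np.mgrid[0 : s.shape[0], 0 : s.shape[1]]
            mass = s.sum()
            r_fine = (float((s * yy).sum() / mass) + 0.5) * f - 0.5
            c_fine = (float((s * xx).sum() / mass) + 0.5) * f - 0.5
            assert abs(r_fine - 63.5) < 1.0
            assert abs(c_fine - 83.5) < 1.0


class TestLosses:
    def test_perfect_generator_limit(self):
        image = np.random.default_rng(1).random((8, 8))
        assert generator_loss(image, image, 1.0 - 1e-9) < 1e-6

    def test_half_score_gives_ln2(self):
        image = np.random.default_rng(2).random((8, 8))
        assert generator_loss(image, image, 0.5) == pytest.approx(np.log(2.0), rel=1e-9)

    def test_compositional_equality(self):
        rng = np.random.default_rng(3)
        gen, truth = rng.random((8, 8)), rng.random((8, 8))
        score = 0.73
        expected = mse_rms(gen, truth) + bce(score, 1.0)
        assert generator_loss(gen, truth, score) == pytest.approx(expected, abs=1e-8)
        expected_d = bce(0.2, 0.0) + bce(0.9, 1.0)
        assert discriminator_loss(0.2, 0.9) == pytest.approx(expected_d, abs=1e-8)

    def test_discriminator_closed_forms(self):
        assert discriminator_loss(1e-9, 1.0 - 1e-9) < 1e-6
        assert discriminator_loss(0.5, 0.5) == pytest.approx(2 * np.log(2.0), rel=1e-9)
        worst = discriminator_loss(1.0 - 1e-9, 1e-9)
        assert worst == pytest.approx(2 * -np.log(1e-7), rel=1e-3)


class TestNetworks:
    def test_generator_output_shape_matches_finest_input(self):
        gen = MultiscaleGenerator(rng=np.random.default_rng(0))
        inputs = [
            s[None, None].astype(np.float32)
            for s in build_multiscale_inputs(np.random.default_rng(1).random((64, 64)))
        ]
        out = gen.forward(inputs)
        assert out.shape == (1, 1, 64, 64)

    def test_discriminator_score_strictly_inside_unit_interval(self):
        disc = Discriminator(DiscriminatorSpec(input_size=32), rng=np.random.default_rng(2))
        x = np.random.default_rng(3).random((3, 1, 32, 32)).astype(np.float32)
        scores = disc.forward_score(x)
        assert np.all(scores > 0.0) and np.all(scores < 1.0)

    def test_single_small_step_decreases_generator_loss(self):
        """Gradient sanity: a tiny plain-gradient step reduces the batch loss."""
        spec = GeneratorSpec(widths=(2, 2, 3, 3), convs_per_scale=2)
        gen = MultiscaleGenerator(spec, rng=np.random.default_rng(4), dtype=np.float64)
        rng = np.random.default_rng(5)
        crops = rng.random((2, 32, 32))
        target = rng.random((2, 1, 32, 32))
        inputs = [
            np.stack(arr)[:, None]
            for arr in zip(*[build_multiscale_inputs(c) for c in crops])
        ]

        def batch_loss():
            out = gen.forward(inputs)
            return float(np.mean((out - target) ** 2)), out

        loss0, out = batch_loss()
        gen.zero_grads()
        gen.backward(2.0 * (out - target) / out.size)
        for p, g in gen.params:
            p -= 1e-7 * g
        loss1, _ = batch_loss()
        assert loss1 < loss0


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_pairs(self):
        from bf2holo.optics import OpticalConfig
        from bf2holo.simulate import make_dataset, render_pair, scene_from_manifest_rows

        optics = OpticalConfig(image_shape=(80, 80))
        manifest = make_dataset(
            22, "unused", seed=13, particle_density=(1, 1),
            depth_range=(20, 80), optics=optics, write_images=False,
        )
        pairs = []
        for _, rows in manifest.groupby("pair_id"):
            bf, holo = render_pair(scene_from_manifest_rows(rows, optics))
            pairs.append((bf, holo))
        return pairs

    def test_zero_iterations_returns_initialization(self, tiny_pairs):
        cfg = TrainConfig.smoke(max_iterations=0, rng_seed=7)
        ckpt, history = train(tiny_pairs[:20], cfg)
        assert history.empty
        assert ckpt.iteration == 0
        ref = MultiscaleGenerator(cfg.generator, rng=np.random.default_rng(
            int(np.random.default_rng(7).integers(2**31))
        ))
        for got, (want, _) in zip(ckpt.gen_weights, ref.params):
            np.testing.assert_array_equal(got, want)

    def test_same_seed_reproduces_history(self, tiny_pairs):
        cfg = TrainConfig.smoke(max_iterations=30, rng_seed=5)
        _, h1 = train(tiny_pairs[:20], cfg, test_pairs=tiny_pairs[20:])
        _, h2 = train(tiny_pairs[:20], cfg, test_pairs=tiny_pairs[20:])
        assert h1.equals(h2)

    def test_smoke_training_reduces_heldout_l2(self, tiny_pairs):
        cfg = TrainConfig.smoke(max_iterations=500, rng_seed=1)
        ckpt, history = train(tiny_pairs[:20], cfg, test_pairs=tiny_pairs[20:])
        untrained = TrainConfig.smoke(max_iterations=0, rng_seed=1)
        ckpt0, _ = train(tiny_pairs[:20], untrained, test_pairs=tiny_pairs[20:])
        from bf2holo.metrics import mse_rms as l2

        initial = np.mean([
            l2(translate(bf, ckpt0).values, holo.values) for bf, holo in tiny_pairs[20:]
        ])
        final = np.mean([
            l2(translate(bf, ckpt).values, holo.values) for bf, holo in tiny_pairs[20:]
        ])
        assert final < initial

    def test_checkpoint_roundtrip(self, tiny_pairs, tmp_path):
        cfg = TrainConfig.smoke(max_iterations=5, rng_seed=2)
        ckpt, _ = train(tiny_pairs[:20], cfg)
        path = tmp_path / "ckpt.npz"
        ckpt.save(path)
        loaded = Checkpoint.load(path)
        assert loaded.iteration == ckpt.iteration
        assert loaded.config == ckpt.config
        for a, b in zip(loaded.gen_weights, ckpt.gen_weights):
            np.testing.assert_array_equal(a, b)

    def test_mismatched_pair_skipped_with_warning(self, tiny_pairs):
        bad = (np.zeros((64, 64)), np.zeros((32, 32)))
        cfg = TrainConfig.smoke(max_iterations=1, rng_seed=3)
        with pytest.warns(UserWarning, match="mismatched"):
            train(list(tiny_pairs[:4]) + [bad], cfg)


class TestTranslate:
    @pytest.fixture(scope="class")
    def untrained_ckpt(self):
        gen = MultiscaleGenerator(rng=np.random.default_rng(1))
        disc = Discriminator(rng=np.random.default_rng(2))
        return Checkpoint(
            [p.copy() for p, _ in gen.params],
            [p.copy() for p, _ in disc.params],
            TrainConfig.smoke(max_iterations=0),
            0,
        )

    def test_output_shape_preserved_for_indivisible_input(self, untrained_ckpt):
        bf = np.random.default_rng(4).random((100, 108))
        with pytest.warns(UserWarning, match="not divisible"):
            out = translate(bf, untrained_ckpt)
        assert out.shape == (100, 108)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_constant_input_gives_finite_smooth_output(self, untrained_ckpt):
        out = translate(np.full((64, 64), 0.5), untrained_ckpt)
        assert np.all(np.isfinite(out))
        assert np.abs(np.diff(out, axis=0)).max() < 0.5

    def test_hologram_container_with_metadata(self, untrained_ckpt):
        from bf2holo.images import BFImage, Hologram
        from bf2holo.optics import OpticalConfig

        optics = OpticalConfig(image_shape=(64, 64))
        bf = BFImage(np.full((64, 64), 0.5), optics)
        out = translate(bf, untrained_ckpt)
        assert isinstance(out, Hologram)
        assert out.provenance == "generated"
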