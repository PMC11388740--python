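"""Cover-synthesis GAN: architecture contracts, losses, smoke training."""

import numpy as np
import pytest

from irbedpose import fixtures, gan, nn
from irbedpose.core import IRFrame
from irbedpose.models import _resize_nearest_np


@pytest.fixture(scope="module")
def small_frames():
    unc = [IRFrame(_resize_nearest_np(f.pixels, 48, 48))
           for f, _ in fixtures.generate_eval_set(6, 1, noise_sigma=0)]
    cov = [IRFrame(_resize_nearest_np(f.pixels, 48, 48), "thin")
           for f, _ in fixtures.generate_eval_set(6, 2, covered=True,
                                                  noise_sigma=0)]
    return unc, cov


class TestGenerator:
    def test_output_shape_preserved(self, small_frames):
        unc, cov = small_frames
        g = gan.build_generator(0.125, frame_shape=(48, 48), seed=0)
        xu = np.stack([f.pixels for f in unc[:2]])[:, None]
        xc = np.stack([f.pixels for f in cov[:2]])[:, None]
        noise = gan.sample_noise(np.random.default_rng(0), 2)
        out = g(xu, xc, noise)
        assert out.shape == xu.shape

    def test_noise_changes_output(self, small_frames):
        unc, cov = small_frames
        g = gan.build_generator(0.125, frame_shape=(48, 48), seed=0).eval()
        xu = unc[0].pixels[None, None]
        xc = cov[0].pixels[None, None]
        rng = np.random.default_rng(1)
        with nn.no_grad():
            a = g(xu, xc, gan.sample_noise(rng, 1)).data
            b = g(xu, xc, gan.sample_noise(rng, 1)).data
        assert not np.allclose(a, b)

    def test_mismatched_shapes_rejected(self, small_frames):
        unc, cov = small_frames
        g = gan.build_generator(0.125, frame_shape=(48, 48), seed=0)
        with pytest.raises(ValueError):
            g(unc[0].pixels[None, None], cov[0].pixels[None, None, :, :24],
              gan.sample_noise(np.random.default_rng(0), 1))

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            gan.build_generator(0.0)


class TestGanDiscriminator:
    def test_one_sixteenth_output_map(self):
        d = gan.build_gan_discriminator(0.125, seed=0)
        x = np.random.default_rng(0).uniform(size=(1, 1, 160, 128))
        out = d(x)
        assert out.shape == (1, 1, 10, 8)
        assert np.isfinite(out.data).all()

    def test_non_divisible_input_rejected(self):
        d = gan.build_gan_discriminator(0.125, seed=0)
        with pytest.raises(ValueError, match="pad"):
            d(np.zeros((1, 1, 160, 120)))

    def test_padding_helper_reaches_divisibility(self):
        padded = gan.pad_for_discriminator(np.zeros((1, 1, 160, 120)))
        assert padded.shape == (1, 1, 160, 128)


class TestGeneratorLoss:
    def test_perfect_generator_case_vanishes(self):
        xu = np.full((1, 1, 8, 8), 0.8)
        xc = np.full((1, 1, 8, 8), 0.4)
        xs = xu * (0.4 / 0.8)
        d_out = np.ones((1, 1, 1, 1))
        total, comps = gan.generator_loss(xs, xu, xc, d_out)
        for key in ("g1", "g2", "g3", "g4"):
            val = comps[key]
            val = val.item() if hasattr(val, "item") else float(val)
            # g4 carries the epsilon used to keep the std differentiable
            assert val == pytest.approx(0.0, abs=1e-9)

    def test_constant_frames_zero_g2_g3(self):
        xu = np.full((1, 1, 8, 8), 0.8)
        xc = np.full((1, 1, 8, 8), 0.4)
        xs = np.full((1, 1, 8, 8), 0.4)
        _, comps = gan.generator_loss(xs, xu, xc)
        assert comps["g2"].item() == pytest.approx(0.0, abs=1e-12)
        assert comps["g3"].item() == pytest.approx(0.0, abs=1e-12)

    def test_g3_closed_form(self):
        xu = np.full((1, 1, 8, 8), 0.5)
        xc = np.full((1, 1, 8, 8), 0.3)
        xs = np.full((1, 1, 8, 8), 0.5)
        _, comps = gan.generator_loss(xs, xu, xc)
        assert comps["g3"].item() == pytest.approx(0.04, abs=1e-9)

    def test_zero_mean_xu_rejected(self):
        with pytest.raises(ValueError):
            gan.generator_loss(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 4, 4)),
                               np.full((1, 1, 4, 4), 0.3))

    def test_components_non_negative(self):
        rng = np.random.default_rng(0)
        xs = rng.uniform(size=(2, 1, 8, 8))
        xu = rng.uniform(0.1, 1.0, size=(2, 1, 8, 8))
        xc = rng.uniform(size=(2, 1, 8, 8))
        total, comps = gan.generator_loss(xs, xu, xc, rng.uniform(size=(2, 1, 1, 1)))
        for v in comps.values():
            assert (v.item() if hasattr(v, "item") else float(v)) >= 0.0


class TestGanDiscriminatorLoss:
    def test_perfect_discriminator(self):
        ones = np.ones((1, 1, 4, 4))
        zeros = np.zeros((1, 1, 4, 4))
        assert gan.gan_discriminator_loss(ones, zeros).item() == \
            pytest.approx(0.0)

    def test_uninformative_half_maps(self):
        half = np.full((1, 1, 4, 4), 0.5)
        assert gan.gan_discriminator_loss(half, half).item() == \
            pytest.approx(0.25)

    def test_symmetry_for_constant_maps(self):
        a = np.full((1, 1, 4, 4), 0.3)
        b = np.full((1, 1, 4, 4), 0.8)
        lhs = gan.gan_discriminator_loss(a, b).item()
        rhs = gan.gan_discriminator_loss(1.0 - b, 1.0 - a).item()
        assert lhs == pytest.approx(rhs)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gan.gan_discriminator_loss(np.ones((1, 1, 4, 4)),
                                       np.zeros((1, 1, 4, 5)))


class TestTrainGan:
    def test_smoke_schedule_and_descent(self, small_frames):
        unc, cov = small_frames
        g, d, history = gan.train_gan(unc, cov, width_multiplier=0.125,
                                      warmup_epochs=4, adversarial_epochs=2,
                                      batch_size=3, rng_seed=0, lr=2e-3)
        assert len(history) == 6
        # per-epoch exponential decay of the learning rate
        for k, entry in enumerate(history):
            assert entry["lr"] == pytest.approx(2e-3 * 0.9 ** k)
        content = [h["g2"] + h["g3"] + h["g4"] for h in history]
        assert content[3] < content[0]  # phase-A descent
        for h in history:
            for key in ("g2", "g3", "g4"):
                assert np.isfinite(h[key]) and h[key] >= 0.0
        assert "d" in history[-1] and np.isfinite(history[-1]["d"])

    def test_requires_both_domains(self, small_frames):
        unc, cov = small_frames
        with pytest.raises(ValueError):
            gan.train_gan(unc, [], rng_seed=0)
        with pytest.raises(ValueError):
            gan.train_gan([], cov, rng_seed=0)

    def test_synthesize_clips_to_unit_range(self, small_frames):
        unc, cov = small_frames
        g = gan.build_generator(0.125, frame_shape=(48, 48), seed=0).eval()
        xs = g.synthesize(unc[0], cov[0], 7)
        assert xs.cover_state == "synthetic"
        assert xs.pixels.min() >= 0.0 and xs.pixels.max() <= 1.0


def test_gan_batch_noise_range_validation(small_frames):
    unc, cov = small_frames
    with pytest.raises(ValueError):
        gan.GanBatch(unc[0], cov[0], np.array([0.7]))
    batch = gan.GanBatch(unc[0], cov[0], np.array([0.5, -0.5]))
    assert batch.synthetic is None
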