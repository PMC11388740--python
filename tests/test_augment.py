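"""Statistical cover augmentation and miscellaneous augmentations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irbedpose import augment, fixtures
from irbedpose.core import IRFrame, Pose


def two_block_frame(upper_value, lower_value, h=16, w=16):
    px = np.full((h, w), lower_value)
    px[: h // 4] = upper_value
    return IRFrame(px, cover_state="thin")


class TestAttenuate:
    def test_zero_thickness_is_identity(self):
        assert augment.attenuate(0.8, 2.3, 0.0) == pytest.approx(0.8)

    def test_zero_alpha_is_identity(self):
        assert augment.attenuate(0.8, 0.0, 3.0) == pytest.approx(0.8)

    def test_closed_form_half(self):
        assert augment.attenuate(1.0, np.log(2), 1.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("alpha,x", [(-1, 1), (1, -1)])
    def test_negative_parameters_rejected(self, alpha, x):
        with pytest.raises(ValueError):
            augment.attenuate(0.5, alpha, x)


class TestEstimateAttenuationFactors:
    def test_direct_ratio_on_two_block_image(self):
        bank = augment.estimate_attenuation_factors([two_block_frame(0.8, 0.4)])
        assert bank.factors == [pytest.approx(0.5)]

    def test_equal_maxima_give_unity(self):
        bank = augment.estimate_attenuation_factors([two_block_frame(0.7, 0.7)])
        assert bank.factors == [pytest.approx(1.0)]

    def test_parameter_recovery_on_fixtures(self):
        frames = fixtures.build_recovery_frames(0.6, 12, rng_seed=5)
        bank = augment.estimate_attenuation_factors(frames)
        assert abs(bank.mean() - 0.6) <= 0.05

    def test_hotter_lower_region_discarded(self):
        bank = augment.estimate_attenuation_factors(
            [two_block_frame(0.4, 0.8), two_block_frame(0.8, 0.4)])
        assert bank.factors == [pytest.approx(0.5)]
        assert bank.source_count == 2

    def test_zero_upper_region_skipped_with_warning(self, caplog):
        frames = [two_block_frame(0.0, 0.4), two_block_frame(0.8, 0.4)]
        with caplog.at_level("WARNING"):
            bank = augment.estimate_attenuation_factors(frames)
        assert bank.factors == [pytest.approx(0.5)]
        assert any("skipped" in r.message for r in caplog.records)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            augment.estimate_attenuation_factors([])


class TestBodyMask:
    def test_uniform_zero_frame_empty_mask(self):
        frame = IRFrame(np.zeros((16, 16)))
        mask = augment.body_mask(frame, 0.5)
        assert not mask.mask.any()

    def test_two_level_exact_selection(self):
        px = np.full((16, 16), 0.1)
        px[4:8, 4:8] = 0.9
        mask = augment.body_mask(IRFrame(px), 0.5)
        assert np.array_equal(mask.mask, px == 0.9)

    def test_otsu_covers_body(self, sample_frame):
        mask = augment.body_mask(sample_frame, "otsu")
        body = sample_frame.pixels >= 0.85 / 2
        assert (mask.mask & body).sum() >= 0.95 * body.sum()

    def test_threshold_out_of_range_rejected(self, sample_frame):
        with pytest.raises(ValueError):
            augment.body_mask(sample_frame, 1.5)


class TestWrinkleMap:
    def test_deterministic(self):
        a = augment.generate_wrinkle_map((32, 24), 5, 0.5)
        b = augment.generate_wrinkle_map((32, 24), 5, 0.5)
        assert np.array_equal(a.values, b.values)

    def test_range_and_limit(self):
        wm = augment.generate_wrinkle_map((32, 24), 1, 1.0)
        assert wm.values.min() >= 0.5 - 1e-12
        assert wm.values.max() <= 1.0
        nearly_flat = augment.generate_wrinkle_map((32, 24), 1, 1e-6)
        assert nearly_flat.values.min() > 1.0 - 1e-6

    def test_seeds_produce_distinct_fields(self):
        maps = [augment.generate_wrinkle_map((32, 24), s, 0.5).values
                for s in range(10)]
        for i in range(10):
            for j in range(i + 1, 10):
                frac = np.mean(np.abs(maps[i] - maps[j]) > 1e-9)
                assert frac >= 0.10

    def test_bad_roughness_rejected(self):
        with pytest.raises(ValueError):
            augment.generate_wrinkle_map((8, 8), 0, 0.0)


class TestSynthesizeCover:
    def setup_method(self):
        self.frame = IRFrame(np.full((40, 32), 0.8))
        self.mask = augment.BodyMask(np.ones((40, 32), bool), 0.5)
        self.flat = augment.WrinkleMap(np.ones((40, 32)))

    def test_unit_factor_flat_wrinkle_is_identity(self):
        out = augment.synthesize_cover(self.frame, self.mask, 1.0, self.flat,
                                       (10, 40))
        assert np.array_equal(out.pixels, self.frame.pixels)
        assert out.cover_state == "synthetic"

    def test_direct_product(self):
        out = augment.synthesize_cover(self.frame, self.mask, 0.5, self.flat,
                                       (10, 40))
        assert np.allclose(out.pixels[10:], 0.4)

    def test_locality_outside_region(self):
        wrinkle = augment.generate_wrinkle_map((40, 32), 3, 0.8)
        out = augment.synthesize_cover(self.frame, self.mask, 0.5, wrinkle,
                                       (20, 30))
        assert np.array_equal(out.pixels[:20], self.frame.pixels[:20])
        assert np.array_equal(out.pixels[30:], self.frame.pixels[30:])

    def test_never_brightens(self):
        wrinkle = augment.generate_wrinkle_map((40, 32), 3, 1.0)
        out = augment.synthesize_cover(self.frame, self.mask, 0.9, wrinkle,
                                       (10, 40))
        assert (out.pixels <= self.frame.pixels + 1e-12).all()

    def test_region_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            augment.synthesize_cover(self.frame, self.mask, 0.5, self.flat,
                                     (10, 60))

    def test_region_in_upper_quarter_rejected(self):
        with pytest.raises(ValueError, match="three-fourths"):
            augment.synthesize_cover(self.frame, self.mask, 0.5, self.flat,
                                     (2, 40))


class TestSensorNoise:
    def test_zero_sigma_identity(self, sample_frame):
        out = augment.add_sensor_noise(sample_frame, 0.0, 1)
        assert np.array_equal(out.pixels, sample_frame.pixels)

    def test_moments(self):
        frame = IRFrame(np.full((200, 200), 0.5))
        out = augment.add_sensor_noise(frame, 0.05, 2)
        noise = out.pixels - 0.5
        assert abs(noise.mean()) < 0.01
        assert abs(noise.std() - 0.05) < 0.01

    def test_deterministic(self, sample_frame):
        a = augment.add_sensor_noise(sample_frame, 0.05, 3)
        b = augment.add_sensor_noise(sample_frame, 0.05, 3)
        assert np.array_equal(a.pixels, b.pixels)


class TestOcclusion:
    def test_zero_attenuation_blanks_region(self, sample_frame):
        out = augment.occlude_random_region(sample_frame, 1, 0.05, 0.0)
        changed = out.pixels != sample_frame.pixels
        assert changed.any()
        assert (out.pixels[changed] == 0.0).all()

    def test_area_budget(self):
        frame = IRFrame(np.full((160, 120), 0.5))
        out = augment.occlude_random_region(frame, 2, 0.01, 0.0)
        assert (out.pixels != frame.pixels).sum() <= 192

    def test_deterministic(self, sample_frame):
        a = augment.occlude_random_region(sample_frame, 7, 0.05, 0.1)
        b = augment.occlude_random_region(sample_frame, 7, 0.05, 0.1)
        assert np.array_equal(a.pixels, b.pixels)


class TestHflip:
    def test_involution(self, sample_frame, sample_pose):
        f1, p1 = augment.hflip(sample_frame, sample_pose)
        f2, p2 = augment.hflip(f1, p1)
        assert np.array_equal(f2.pixels, sample_frame.pixels)
        # (w-1) - x applied twice recovers x up to one rounding of the mirror
        assert np.allclose(p2.keypoints, sample_pose.keypoints, atol=1e-10,
                           rtol=0)

    def test_boundary_coordinate(self, sample_frame, sample_pose):
        kps = sample_pose.keypoints.copy()
        kps[0] = (0.0, 50.0)
        _, flipped = augment.hflip(sample_frame, Pose(kps))
        # right ankle slot now holds the mirrored left ankle; the flipped
        # original right ankle sits in the left slot at x = width - 1
        assert flipped.keypoints[5, 0] == pytest.approx(119.0)

    def test_mirror_pair_swap_by_hand(self, sample_frame, sample_pose):
        kps = sample_pose.keypoints.copy()
        kps[6] = (10.0, 50.0)    # right wrist
        kps[11] = (100.0, 50.0)  # left wrist
        _, flipped = augment.hflip(sample_frame, Pose(kps))
        assert tuple(flipped.keypoints[6]) == pytest.approx((19.0, 50.0))
        assert tuple(flipped.keypoints[11]) == pytest.approx((109.0, 50.0))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), sigma=st.floats(0.0, 0.2))
def test_stochastic_ops_preserve_shape_and_range(seed, sigma):
    pose = fixtures.generate_subject_pose(seed % 50, "supine")
    frame = fixtures.render_frame(pose, seed % 7)
    out = augment.add_sensor_noise(frame, sigma, seed)
    out = augment.occlude_random_region(out, seed, 0.05, 0.2)
    out, _ = augment.hflip(out)
    assert out.pixels.shape == frame.pixels.shape
    assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0


def test_pipeline_is_pure_function_of_seed(sample_frame, sample_pose):
    bank = augment.AttenuationBank([0.5, 0.6])
    pipe = augment.AugmentationPipeline(bank)
    outs = []
    for _ in range(2):
        rng = np.random.default_rng(123)
        f, p = pipe(sample_frame, sample_pose, rng)
        outs.append((f.pixels, p.keypoints))
    assert np.array_equal(outs[0][0], outs[1][0])
    assert np.array_equal(outs[0][1], outs[1][1])
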