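"""Heatmap encoding, sub-pixel decoding and flip-averaged inference."""

import numpy as np
import pytest

from irbedpose import heatmaps
from irbedpose.core import N_KEYPOINTS, Pose
from irbedpose.heatmaps import (HeatmapStack, RefinementParams, argmax_seed,
                                decode_pose, encode_pose, flip_average,
                                radius_at_epoch, refine_keypoint)

from conftest import refine_oracle


def pose_at(points):
    kps = np.full((N_KEYPOINTS, 2), np.nan)
    for i, p in enumerate(points):
        kps[i] = p
    return Pose(kps)


class TestRadiusSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 3.0), (15, 2.0), (30, 1.0), (45, 1.0), (1000, 1.0)])
    def test_linear_ramp(self, epoch, expected):
        assert radius_at_epoch(epoch) == pytest.approx(expected)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            radius_at_epoch(-1)


class TestEncode:
    def test_peak_at_keypoint(self):
        pose = pose_at([(9.0, 7.0)])
        stack = encode_pose(pose, (24, 24), 1.0, radius=3)
        y, x = np.unravel_index(np.argmax(stack.maps[0]), (24, 24))
        assert (x, y) == (9, 7)

    def test_channels_sum_to_one(self):
        pose = pose_at([(5.0, 5.0), (10.0, 12.0)])
        stack = encode_pose(pose, (24, 24), 1.0, radius=2)
        for i in (0, 1):
            assert stack.maps[i].sum() == pytest.approx(1.0, abs=1e-5)

    def test_out_of_bounds_keypoint_yields_zero_channel(self):
        pose = pose_at([(500.0, 5.0)])
        stack = encode_pose(pose, (24, 24), 1.0, radius=2)
        assert not stack.maps[0].any()

    def test_peak_normalization_mode(self):
        pose = pose_at([(5.0, 5.0)])
        stack = encode_pose(pose, (24, 24), 1.0, radius=2, normalize="peak")
        assert stack.maps[0].max() == pytest.approx(1.0)

    def test_scale_maps_image_to_heatmap_coordinates(self):
        pose = pose_at([(40.0, 80.0)])
        stack = encode_pose(pose, (32, 32), (4.0, 8.0), radius=2)
        y, x = np.unravel_index(np.argmax(stack.maps[0]), (32, 32))
        assert (x, y) == (10, 10)

    def test_invalid_arguments_rejected(self):
        pose = pose_at([(5.0, 5.0)])
        with pytest.raises(ValueError):
            encode_pose(pose, (0, 24), 1.0, radius=2)
        with pytest.raises(ValueError):
            encode_pose(pose, (24, 24), 1.0, radius=0.5)


class TestArgmaxSeed:
    def test_single_nonzero_pixel(self):
        ch = np.zeros((16, 16))
        ch[7, 9] = 1.0
        assert argmax_seed(ch) == (9.0, 7.0)

    def test_tie_breaks_row_major(self):
        ch = np.zeros((16, 16))
        ch[3, 3] = ch[3, 9] = 1.0
        assert argmax_seed(ch) == (3.0, 3.0)

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError, match="undecodable"):
            argmax_seed(np.zeros((8, 8)))


class TestRefineKeypoint:
    def test_symmetric_gaussian_returns_center(self):
        yy, xx = np.mgrid[0:21, 0:21]
        ch = np.exp(-((xx - 10.0) ** 2 + (yy - 10.0) ** 2) / 4.0)
        x, y, ok = refine_keypoint(ch, (10, 10), RefinementParams())
        assert ok
        assert (x, y) == (pytest.approx(10.0), pytest.approx(10.0))

    def test_two_pixel_fixed_point(self):
        ch = np.zeros((21, 21))
        ch[10, 10] = ch[10, 11] = 1.0
        x, y, ok = refine_keypoint(ch, (10, 10),
                                   RefinementParams(window_size=5, iterations=3))
        assert (x, y) == (pytest.approx(10.5), pytest.approx(10.0))

    def test_zero_mass_returns_seed_with_flag(self):
        ch = np.zeros((21, 21))
        ch[0, 0] = 1.0
        x, y, ok = refine_keypoint(ch, (15, 15), RefinementParams())
        assert not ok
        assert (x, y) == (15.0, 15.0)

    def test_oracle_equivalence_on_random_sparse_maps(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            ch = np.zeros((20, 26))
            k = rng.integers(1, 8)
            ys = rng.integers(0, 20, size=k)
            xs = rng.integers(0, 26, size=k)
            ch[ys, xs] = rng.uniform(0.1, 1.0, size=k)
            seed = argmax_seed(ch)
            x, y, _ = refine_keypoint(ch, seed, RefinementParams(5, 3))
            ox, oy = refine_oracle(ch, seed, d=5, n_iter=3)
            assert x == ox and y == oy  # bitwise agreement

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RefinementParams(window_size=4)
        with pytest.raises(ValueError):
            RefinementParams(iterations=-1)


class TestFlipAverage:
    def make_stack(self, maps):
        return HeatmapStack(maps, scale=1.0)

    def test_flip_then_flip_back_is_identity(self):
        rng = np.random.default_rng(0)
        maps = rng.uniform(size=(N_KEYPOINTS, 12, 10))
        stack = self.make_stack(maps)
        # emulate "prediction on the flipped image" by flipping + swapping
        mirrored = maps[:, :, ::-1].copy()
        from irbedpose.core import MIRROR_PAIRS
        for a, b in MIRROR_PAIRS:
            mirrored[[a, b]] = mirrored[[b, a]]
        merged = flip_average(stack, self.make_stack(mirrored))
        assert np.allclose(merged.maps, maps)

    def test_symmetric_peaks_average_to_midline(self):
        maps_a = np.zeros((N_KEYPOINTS, 9, 9))
        maps_b = np.zeros((N_KEYPOINTS, 9, 9))
        maps_a[12, 4, 3] = 1.0              # neck: self-mirrored channel
        maps_b[12, 4, 3] = 1.0              # flipped-back position: col 5
        merged = flip_average(self.make_stack(maps_a),
                              self.make_stack(maps_b))
        assert merged.maps[12, 4, 3] == pytest.approx(0.5)
        assert merged.maps[12, 4, 5] == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        a = self.make_stack(np.zeros((N_KEYPOINTS, 8, 8)))
        b = self.make_stack(np.zeros((N_KEYPOINTS, 8, 10)))
        with pytest.raises(ValueError):
            flip_average(a, b)


class TestDecode:
    def test_round_trip_within_half_pixel(self):
        rng = np.random.default_rng(7)
        for radius in (1, 2, 3):
            kps = np.column_stack([rng.uniform(3, 27, N_KEYPOINTS),
                                   rng.uniform(3, 21, N_KEYPOINTS)])
            pose = Pose(kps)
            stack = encode_pose(pose, (24, 30), 1.0, radius)
            decoded = decode_pose(stack)
            assert np.abs(decoded.keypoints - kps).max() <= 0.5

    def test_scale_returns_image_coordinates(self):
        pose = pose_at([(40.0, 80.0)])
        stack = encode_pose(pose, (32, 32), (4.0, 8.0), radius=2)
        decoded = decode_pose(stack)
        assert decoded.keypoints[0] == pytest.approx((40.0, 80.0), abs=2.0)

    def test_zero_channel_flags_invisible(self):
        stack = HeatmapStack(np.zeros((N_KEYPOINTS, 8, 8)), scale=1.0)
        decoded = decode_pose(stack)
        assert not decoded.visible.any()


def test_stack_container_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    stack = HeatmapStack(rng.uniform(size=(N_KEYPOINTS, 10, 12)),
                         scale=(4.0, 5.0))
    path = tmp_path / "stack.hmz"
    stack.save(path)
    loaded = HeatmapStack.load(path)
    assert np.array_equal(loaded.maps, stack.maps)
    assert np.array_equal(loaded.scale, stack.scale)


def test_stack_validation():
    with pytest.raises(ValueError):
        HeatmapStack(np.zeros((5, 8, 8)))
    with pytest.raises(ValueError):
        HeatmapStack(-np.ones((N_KEYPOINTS, 8, 8)))
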