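"""Gaussian heatmap encoding and sub-pixel decoding of keypoints.

Encoding places one isotropic Gaussian per keypoint on a coarse grid, with a
radius that shrinks linearly over the first training epochs (diffuse targets
early on help the network find rough locations before pinpointing them).
Decoding takes the per-channel argmax as a first estimate and refines it by
iterating an intensity-weighted center of mass over a small window; at test
time heatmaps from the image and its horizontal mirror are averaged first.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .core import N_KEYPOINTS, Pose, get_mirror_pairs

__all__ = [
    "HeatmapStack", "RefinementParams", "radius_at_epoch", "encode_pose",
    "argmax_seed", "refine_keypoint", "flip_average", "decode_pose",
]


def _as_scale(scale) -> np.ndarray:
    """Scale as (sx, sy): heatmap coords * scale = image coords."""
    arr = np.atleast_1d(np.asarray(scale, dtype=np.float64))
    if arr.size == 1:
        arr = np.repeat(arr, 2)
    if arr.size != 2 or np.any(arr <= 0):
        raise ValueError("scale must be a positive scalar or (sx, sy) pair")
    return arr


@dataclass
class HeatmapStack:
    """14 per-keypoint non-negative score maps plus the image/heatmap scale."""

    maps: np.ndarray
    scale: np.ndarray = field(default_factory=lambda: np.ones(2))

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3 or self.maps.shape[0] != N_KEYPOINTS:
            raise ValueError(f"expected ({N_KEYPOINTS}, H, W) maps, "
                             f"got {self.maps.shape}")
        if not np.all(np.isfinite(self.maps)) or self.maps.min() < 0:
            raise ValueError("heatmap scores must be finite and >= 0")
        self.scale = _as_scale(self.scale)

    @property
    def shape(self):
        return self.maps.shape

    def save(self, path) -> None:
        """Write to a zip container: raw array + JSON header."""
        header = {"shape": list(self.maps.shape),
                  "scale": self.scale.tolist(),
                  "dtype": "float64",
                  "channel_order": "lsp14"}
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("header.json", json.dumps(header))
            zf.writestr("maps.bin", self.maps.tobytes())

    @classmethod
    def load(cls, path) -> "HeatmapStack":
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            maps = np.frombuffer(zf.read("maps.bin"),
                                 dtype=header["dtype"]).reshape(header["shape"])
        return cls(maps.copy(), scale=np.asarray(header["scale"]))


@dataclass
class RefinementParams:
    """Center-of-mass refinement: d x d window, N iterations."""

    window_size: int = 5
    iterations: int = 3

    def __post_init__(self):
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 1")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


def radius_at_epoch(epoch: int, start_radius: float = 3.0,
                    end_radius: float = 1.0, ramp_epochs: int = 30) -> float:
    """Linearly shrink the target-Gaussian radius over the first epochs."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if epoch >= ramp_epochs:
        return float(end_radius)
    frac = epoch / ramp_epochs
    return float(start_radius + (end_radius - start_radius) * frac)


def encode_pose(pose: Pose, heatmap_shape, scale, radius: float,
                normalize: str = "sum") -> HeatmapStack:
    """Encode keypoints as truncated Gaussians (sigma = radius / 2, 3-sigma
    support) on a heatmap grid.

    Image coordinates are divided by `scale` to land on the grid.  With
    ``normalize="sum"`` each in-bounds channel sums to 1 (commensurate with a
    spatial-softmax network output); ``normalize="peak"`` leaves the peak at
    1 for raw-MSE training.  Keypoints mapping outside the grid (or NaN)
    yield an all-zero channel, flagging the keypoint invisible.
    """
    hh, ww = int(heatmap_shape[0]), int(heatmap_shape[1])
    if hh <= 0 or ww <= 0:
        raise ValueError("heatmap shape must be positive")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if normalize not in ("sum", "peak"):
        raise ValueError("normalize must be 'sum' or 'peak'")
    sc = _as_scale(scale)
    sigma = radius / 2.0
    support = 3.0 * sigma
    maps = np.zeros((N_KEYPOINTS, hh, ww))
    ys, xs = np.mgrid[0:hh, 0:ww].astype(np.float64)
    for i, (x, y) in enumerate(pose.keypoints):
        if np.isnan(x) or np.isnan(y):
            continue
        cx, cy = x / sc[0], y / sc[1]
        if not (-0.5 <= cx <= ww - 0.5 and -0.5 <= cy <= hh - 0.5):
            continue
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        g = np.exp(-d2 / (2.0 * sigma ** 2))
        g[d2 > support ** 2] = 0.0
        total = g.sum()
        if total <= 0:
            continue
        maps[i] = g / total if normalize == "sum" else g / g.max()
    return HeatmapStack(maps, scale=sc)


def argmax_seed(channel: np.ndarray):
    """Integer (x0, y0) of the channel maximum; ties resolved row-major."""
    channel = np.asarray(channel)
    if channel.max() == channel.min():
        raise ValueError("constant channel: keypoint undecodable")
    flat = int(np.argmax(channel))  # first occurrence = smallest row, then col
    y0, x0 = divmod(flat, channel.shape[1])
    return float(x0), float(y0)


def refine_keypoint(channel: np.ndarray, seed, params: RefinementParams):
    """Iterative center-of-mass refinement around the argmax seed.

    Each iteration rounds the current estimate to the nearest pixel
    (floor(v + 0.5)), forms the d x d window centered there (out-of-bounds
    pixels contribute zero) and moves the estimate to the window's
    intensity-weighted centroid.  If the window mass is zero the seed is
    returned unchanged with ``converged=False``.

    Returns ``(x, y, converged)``.
    """
    channel = np.asarray(channel, dtype=np.float64)
    h, w = channel.shape
    x, y = float(seed[0]), float(seed[1])
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError("seed outside channel bounds")
    half = (params.window_size - 1) // 2
    for _ in range(params.iterations):
        xi = int(np.floor(x + 0.5))
        yi = int(np.floor(y + 0.5))
        sx = sy = mass = 0.0
        x0, x1 = max(xi - half, 0), min(xi + half, w - 1)
        y0, y1 = max(yi - half, 0), min(yi + half, h - 1)
        win = channel[y0:y1 + 1, x0:x1 + 1]
        mass = win.sum()
        if mass <= 0.0:
            return float(seed[0]), float(seed[1]), False
        yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
        sx = float((win * xx).sum())
        sy = float((win * yy).sum())
        x, y = sx / mass, sy / mass
    return x, y, True


def flip_average(stack_original: HeatmapStack,
                 stack_from_flipped: HeatmapStack) -> HeatmapStack:
    """Merge heatmaps predicted on an image and on its horizontal mirror.

    The second stack is mirrored back and its left/right channel pairs are
    swapped (a mirrored image's "left wrist" channel describes the anatomical
    right wrist), then the element-wise mean of the two stacks is taken.
    """
    if stack_original.maps.shape != stack_from_flipped.maps.shape:
        raise ValueError("stacks must have equal shapes")
    unflipped = stack_from_flipped.maps[:, :, ::-1].copy()
    for a, b in get_mirror_pairs():
        unflipped[[a, b]] = unflipped[[b, a]]
    return HeatmapStack(0.5 * (stack_original.maps + unflipped),
                        scale=stack_original.scale)


def decode_pose(stack: HeatmapStack,
                params: RefinementParams | None = None) -> Pose:
    """Decode a stack to sub-pixel image coordinates.

    Per channel: argmax seed, center-of-mass refinement, then scale back to
    image coordinates.  Undecodable (constant, e.g. all-zero) channels yield
    NaN keypoints, i.e. invisible.
    """
    params = params or RefinementParams()
    kps = np.full((N_KEYPOINTS, 2), np.nan)
    for i in range(N_KEYPOINTS):
        channel = stack.maps[i]
        try:
            seed = argmax_seed(channel)
        except ValueError:
            continue
        x, y, _ = refine_keypoint(channel, seed, params)
        kps[i] = (x * stack.scale[0], y * stack.scale[1])
    return Pose(kps)
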