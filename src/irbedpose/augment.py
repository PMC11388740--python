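"""Statistical cover augmentation and miscellaneous image augmentations.

The core idea: a blanket attenuates LWIR emission roughly exponentially in
its thickness, I = I0 * exp(-alpha * x).  Since neither the fabric's
attenuation coefficient alpha nor its effective thickness x is known, only
their product is estimated, as an attenuation *factor*
F = I / I0 = exp(-alpha * x) in (0, 1].  On real covered frames the head
region is typically uncovered, so F is approximated per frame by the ratio of
the brightest pixel in the lower three-fourths (covered body) to the
brightest pixel in the upper fourth (uncovered head/shoulders).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import IRFrame, Pose, get_mirror_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "AttenuationBank", "WrinkleMap", "BodyMask",
    "attenuate", "estimate_attenuation_factors", "body_mask",
    "generate_wrinkle_map", "synthesize_cover", "add_sensor_noise",
    "occlude_random_region", "hflip", "AugmentationPipeline",
]

#: Fraction of wrinkle-free attenuation retained where the wrinkle map is
#: darkest: F_eff = F * (W_FLOOR + (1 - W_FLOOR) * wrinkle).
DEFAULT_WRINKLE_FLOOR = 0.5


@dataclass
class AttenuationBank:
    """Empirical collection of per-frame attenuation-factor estimates."""

    factors: list = field(default_factory=list)
    source_count: int = 0

    def __post_init__(self):
        for f in self.factors:
            if not (0.0 < f <= 1.0):
                raise ValueError(f"attenuation factor {f} outside (0, 1]")

    def sample(self, rng: np.random.Generator) -> float:
        if not self.factors:
            raise ValueError("empty attenuation bank")
        return float(self.factors[rng.integers(len(self.factors))])

    def mean(self) -> float:
        return float(np.mean(self.factors))

    def to_json(self) -> list:
        return [float(f) for f in self.factors]


@dataclass
class WrinkleMap:
    """Multiplicative cloth-fold field: 1 = flat cloth, lower = folded."""

    values: np.ndarray
    seed: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("wrinkle values must lie in [0, 1]")


@dataclass
class BodyMask:
    mask: np.ndarray
    threshold_used: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)


def attenuate(intensity: float, alpha: float, thickness: float) -> float:
    """Beer-Lambert attenuation I = I0 * exp(-alpha * x)."""
    if alpha < 0 or thickness < 0:
        raise ValueError("alpha and thickness must be non-negative")
    if not 0.0 <= intensity <= 1.0:
        raise ValueError("intensity must lie in [0, 1]")
    return float(intensity * np.exp(-alpha * thickness))


def estimate_attenuation_factors(covered_frames, upper_fraction: float = 0.25,
                                 ) -> AttenuationBank:
    """Estimate F per frame as max(lower region) / max(upper region).

    The upper `upper_fraction` of rows is assumed to show uncovered body
    (the head), the remaining rows the covered body.  Estimates > 1 violate
    that assumption (lower region hotter than the head) and are discarded;
    frames whose upper region is entirely zero are skipped with a warning.
    """
    frames = list(covered_frames)
    if not frames:
        raise ValueError("need at least one covered frame")
    if not 0.0 < upper_fraction < 1.0:
        raise ValueError("upper_fraction must lie in (0, 1)")
    factors = []
    for i, frame in enumerate(frames):
        split = max(int(round(frame.height * upper_fraction)), 1)
        upper_max = float(frame.pixels[:split].max())
        lower_max = float(frame.pixels[split:].max())
        if upper_max <= 0.0:
            logger.warning("frame %d: upper region all zero, skipped", i)
            continue
        f = lower_max / upper_max
        if f > 1.0 or f <= 0.0:
            logger.warning("frame %d: estimated F=%.3f outside (0, 1], "
                           "discarded", i, f)
            continue
        factors.append(f)
    return AttenuationBank(factors=factors, source_count=len(frames))


def body_mask(frame: IRFrame, threshold="otsu") -> BodyMask:
    """Threshold segmentation of the (warm) subject against the background."""
    if threshold == "otsu":
        thr = float(threshold_otsu(frame.pixels))
    else:
        thr = float(threshold)
        if not 0.0 <= thr <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
    return BodyMask(mask=frame.pixels > thr, threshold_used=thr)


def generate_wrinkle_map(shape, rng_seed: int, roughness: float,
                         correlation_px: float = 8.0,
                         spread: float = 0.5) -> WrinkleMap:
    """Band-limited smooth random field standing in for rendered cloth folds.

    White noise is low-pass filtered at `correlation_px` and rescaled to
    [1 - roughness * spread, 1]; darker values mark folded (more attenuating)
    cloth.  As roughness -> 0 the map tends to the constant flat-cloth value 1.
    """
    if not 0.0 < roughness <= 1.0:
        raise ValueError("roughness must lie in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=correlation_px, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    unit = (smooth - lo) / (hi - lo) if hi > lo else np.ones(shape)
    depth = roughness * spread
    values = (1.0 - depth) + depth * unit
    return WrinkleMap(values=values, seed=int(rng_seed))


def synthesize_cover(frame: IRFrame, mask: BodyMask, factor: float,
                     wrinkle: WrinkleMap, region,
                     wrinkle_floor: float = DEFAULT_WRINKLE_FLOOR) -> IRFrame:
    """Attenuate the masked body pixels within a row band to fake a blanket.

    ``region`` is a half-open row interval (top, bottom); it must lie in the
    lower three-fourths of the frame (the head stays uncovered).  Inside
    mask-and-region, out = in * F_eff with
    F_eff = factor * (wrinkle_floor + (1 - wrinkle_floor) * wrinkle); every
    other pixel is bitwise unchanged, and no pixel ever gets brighter.
    """
    top, bottom = int(region[0]), int(region[1])
    h = frame.height
    if not (0 <= top <= bottom <= h):
        raise ValueError(f"region {region} outside frame rows [0, {h}]")
    if top < h // 4:
        raise ValueError("cover region must lie in the lower three-fourths")
    if not 0.0 < factor <= 1.0:
        raise ValueError("attenuation factor must lie in (0, 1]")
    if wrinkle.values.shape != frame.pixels.shape:
        raise ValueError("wrinkle map shape must match the frame")
    if mask.mask.shape != frame.pixels.shape:
        raise ValueError("mask shape must match the frame")
    out = frame.pixels.copy()
    sel = np.zeros_like(mask.mask)
    sel[top:bottom] = mask.mask[top:bottom]
    f_eff = factor * (wrinkle_floor + (1.0 - wrinkle_floor) * wrinkle.values)
    out[sel] = out[sel] * f_eff[sel]
    return IRFrame(out, cover_state="synthetic")


def add_sensor_noise(frame: IRFrame, sigma: float, rng_seed: int) -> IRFrame:
    """Zero-mean Gaussian sensor noise, clipped back to [0, 1]."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return frame.copy()
    rng = np.random.default_rng(rng_seed)
    noisy = frame.pixels + rng.normal(0.0, sigma, size=frame.pixels.shape)
    return IRFrame(np.clip(noisy, 0.0, 1.0), cover_state=frame.cover_state)


def occlude_random_region(frame: IRFrame, rng_seed: int,
                          max_area_fraction: float,
                          attenuation: float) -> IRFrame:
    """Heavily attenuate one random rectangle (simulated full obstruction)."""
    if not 0.0 < max_area_fraction < 1.0:
        raise ValueError("max_area_fraction must lie in (0, 1)")
    if not 0.0 <= attenuation < 1.0:
        raise ValueError("attenuation must lie in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    h, w = frame.pixels.shape
    max_area = max_area_fraction * h * w
    # sample an aspect ratio, then fit the rectangle to the area budget
    aspect = rng.uniform(0.5, 2.0)
    rh = max(int(np.sqrt(max_area * aspect)), 1)
    rw = max(int(max_area // rh), 1)
    rh, rw = min(rh, h), min(rw, w)
    top = int(rng.integers(0, h - rh + 1))
    left = int(rng.integers(0, w - rw + 1))
    out = frame.pixels.copy()
    out[top:top + rh, left:left + rw] *= attenuation
    return IRFrame(out, cover_state=frame.cover_state)


def hflip(frame: IRFrame, pose: Pose | None = None):
    """Mirror the frame about the vertical axis; swap left/right keypoints.

    Keypoint x maps to (width - 1) - x and mirror-paired joint slots are
    exchanged so channel semantics stay anatomically correct.  The operation
    is an involution.
    """
    flipped = IRFrame(frame.pixels[:, ::-1].copy(), cover_state=frame.cover_state)
    if pose is None:
        return flipped, None
    kps = pose.keypoints.copy()
    kps[:, 0] = (frame.width - 1) - kps[:, 0]
    for a, b in get_mirror_pairs():
        kps[[a, b]] = kps[[b, a]]
    return flipped, Pose(kps)


class AugmentationPipeline:
    """On-the-fly compounding of cover / noise / occlusion / flip.

    Each call independently applies synthetic-cover, sensor-noise, heavy
    occlusion, and horizontal-flip augmentations with the configured
    probabilities; the cover attenuation factor is sampled per image from
    the attenuation bank.
    """

    def __init__(self, bank: AttenuationBank | None,
                 p_cover: float = 0.8, p_noise: float = 0.5,
                 p_occlude: float = 0.3, p_flip: float = 0.5,
                 noise_sigma: float = 0.02, occlude_area: float = 0.04,
                 occlude_attenuation: float = 0.1,
                 wrinkle_roughness: float = 0.5,
                 wrinkle_floor: float = DEFAULT_WRINKLE_FLOOR,
                 cover_top_range=(0.25, 0.6)):
        self.bank = bank
        self.p_cover, self.p_noise = p_cover, p_noise
        self.p_occlude, self.p_flip = p_occlude, p_flip
        self.noise_sigma = noise_sigma
        self.occlude_area = occlude_area
        self.occlude_attenuation = occlude_attenuation
        self.wrinkle_roughness = wrinkle_roughness
        self.wrinkle_floor = wrinkle_floor
        self.cover_top_range = cover_top_range

    def __call__(self, frame: IRFrame, pose: Pose | None,
                 rng: np.random.Generator):
        if self.bank is not None and self.bank.factors and \
                rng.random() < self.p_cover:
            h = frame.height
            lo, hi = self.cover_top_range
            top = int(rng.uniform(lo, hi) * h)
            top = max(top, h // 4)
            wr = generate_wrinkle_map(frame.pixels.shape,
                                      int(rng.integers(2 ** 31)),
                                      self.wrinkle_roughness)
            mask = body_mask(frame, "otsu")
            if mask.mask.any():
                frame = synthesize_cover(frame, mask, self.bank.sample(rng),
                                         wr, (top, h),
                                         wrinkle_floor=self.wrinkle_floor)
        if self.p_noise > 0 and rng.random() < self.p_noise:
            frame = add_sensor_noise(frame, self.noise_sigma,
                                     int(rng.integers(2 ** 31)))
        if self.p_occlude > 0 and rng.random() < self.p_occlude:
            frame = occlude_random_region(frame, int(rng.integers(2 ** 31)),
                                          self.occlude_area,
                                          self.occlude_attenuation)
        if rng.random() < self.p_flip:
            frame, pose = hflip(frame, pose)
        return frame, pose
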