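"""Synthetic LWIR-like in-bed scene generator.

Real long-wavelength infrared recordings of lying subjects are not
redistributable, so every other module in this package is exercised on
procedurally generated scenes: an articulated 14-joint skeleton sampled from
lying-pose joint-angle ranges, rendered as a warm body (anti-aliased capsule
limbs, disk head) against a cool background at the 160x120 resolution typical
of low-cost thermal cameras.  Covered variants are produced by the package's
own statistical cover synthesis with the true attenuation factor recorded in
a sidecar file, which makes attenuation-estimation recovery testable against
ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from . import augment
from .core import (
    DatasetManifest, IRFrame, ManifestRecord, Pose,
    HEAD_TOP, NECK, SKELETON_EDGES,
)

__all__ = [
    "POSE_FAMILIES", "LIMB_LENGTH_BOUNDS",
    "generate_subject_pose", "render_frame", "build_manifest",
    "build_recovery_frames", "load_manifest", "load_frame", "save_frame",
    "generate_eval_set",
]

FRAME_HEIGHT, FRAME_WIDTH = 160, 120

POSE_FAMILIES = ("supine", "side-left", "side-right")

#: Sampling bounds for each limb segment length (pixels).  Keys are skeleton
#: edges (joint index pairs); tests assert generated poses respect these.
LIMB_LENGTH_BOUNDS = {
    (12, 8): (8.0, 12.0),    # neck -> r_shoulder
    (12, 9): (8.0, 12.0),    # neck -> l_shoulder
    (8, 7): (16.0, 22.0),    # upper arm
    (9, 10): (16.0, 22.0),
    (7, 6): (14.0, 20.0),    # forearm
    (10, 11): (14.0, 20.0),
    (2, 3): (12.0, 17.0),    # pelvis width
    (2, 1): (24.0, 30.0),    # thigh
    (3, 4): (24.0, 30.0),
    (1, 0): (22.0, 28.0),    # shin
    (4, 5): (22.0, 28.0),
}

HEAD_NECK_BOUNDS = (12.0, 16.0)
TORSO_BOUNDS = (40.0, 50.0)


def _polar(origin, length, angle, side):
    """Point at `length` from origin; angle measured from the +y (down) axis,
    positive swinging toward the subject's `side` (+1 left / -1 right)."""
    return origin + np.array([side * length * np.sin(angle),
                              length * np.cos(angle)])


def generate_subject_pose(rng_seed: int, pose_family: str = "supine",
                          height: int = FRAME_HEIGHT,
                          width: int = FRAME_WIDTH) -> Pose:
    """Sample an articulated lying-body skeleton.

    Head-top and neck always land in the upper quarter of the frame (the
    convention the attenuation estimator relies on); limb segment lengths are
    drawn from :data:`LIMB_LENGTH_BOUNDS` and joint angles from ranges
    plausible for supine or side-lying postures.
    """
    if pose_family not in POSE_FAMILIES:
        raise ValueError(f"unknown pose family {pose_family!r}; "
                         f"expected one of {POSE_FAMILIES}")
    rng = np.random.default_rng(rng_seed)
    u = rng.uniform

    def seg(edge):
        lo, hi = LIMB_LENGTH_BOUNDS[edge]
        return u(lo, hi)

    lean = {"supine": 0.0, "side-left": np.deg2rad(12),
            "side-right": -np.deg2rad(12)}[pose_family]
    bend = {"supine": 0.0, "side-left": np.deg2rad(28),
            "side-right": -np.deg2rad(28)}[pose_family]

    kps = np.zeros((14, 2))
    cx = width / 2 + u(-8, 8)
    head_top = np.array([cx + u(-3, 3), u(10, 0.25 * height - HEAD_NECK_BOUNDS[1] - 4)])
    l = u(*HEAD_NECK_BOUNDS)
    neck = head_top + np.array([u(-2, 2), l])
    kps[HEAD_TOP], kps[NECK] = head_top, neck

    for side, idx in ((-1, 8), (1, 9)):          # right shoulder at smaller x
        sw = seg((12, idx))
        dy = u(1, 3)
        kps[idx] = neck + np.array([side * np.sqrt(sw ** 2 - dy ** 2), dy])

    torso = u(*TORSO_BOUNDS)
    mid_hip = neck + np.array([torso * np.sin(lean) + u(-3, 3),
                               torso * np.cos(lean)])
    pw = seg((2, 3))
    kps[2] = mid_hip + np.array([-pw / 2, 0.0])
    kps[3] = mid_hip + np.array([pw / 2, 0.0])

    for side, sh, el, wr in ((-1, 8, 7, 6), (1, 9, 10, 11)):
        a1 = np.deg2rad(u(5, 40)) + side * bend * 0.5
        a2 = a1 + np.deg2rad(u(-20, 45))
        kps[el] = _polar(kps[sh], seg((sh, el)), a1, side)
        kps[wr] = _polar(kps[el], seg((el, wr)), a2, side)

    for side, hp, kn, an in ((-1, 2, 1, 0), (1, 3, 4, 5)):
        a1 = np.deg2rad(u(-5, 14)) + side * bend
        a2 = a1 + side * abs(bend) * 1.6 + np.deg2rad(u(-6, 6))
        kps[kn] = _polar(kps[hp], seg((hp, kn)), a1, side)
        kps[an] = _polar(kps[kn], seg((kn, an)), a2, side)

    # keep everything renderable inside the frame
    kps[:, 0] = np.clip(kps[:, 0], 6, width - 7)
    kps[:, 1] = np.clip(kps[:, 1], 4, height - 5)
    return Pose(kps)


# capsule radius per skeleton edge (pixels)
_EDGE_RADIUS = {
    (12, 8): 6.0, (12, 9): 6.0,
    (8, 7): 3.5, (7, 6): 3.0, (9, 10): 3.5, (10, 11): 3.0,
    (2, 3): 7.0, (2, 1): 4.5, (1, 0): 3.5, (3, 4): 4.5, (4, 5): 3.5,
}
_TORSO_RADIUS = 9.0


def _capsule_coverage(yy, xx, p0, p1, radius):
    """Anti-aliased coverage in [0, 1] of a capsule from p0 to p1."""
    d = p1 - p0
    denom = float(d @ d)
    if denom < 1e-12:
        dist = np.hypot(xx - p0[0], yy - p0[1])
    else:
        t = ((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / denom
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(xx - (p0[0] + t * d[0]), yy - (p0[1] + t * d[1]))
    return np.clip(radius + 0.5 - dist, 0.0, 1.0)


def render_frame(pose: Pose, rng_seed: int, body_intensity: float = 0.85,
                 background_intensity: float = 0.10,
                 height: int = FRAME_HEIGHT, width: int = FRAME_WIDTH,
                 intensity_jitter: float = 0.02) -> IRFrame:
    """Render a pose as a warm body on a cool background.

    Limbs become anti-aliased capsules between connected joints, the torso a
    thick capsule from neck to pelvis midpoint, the head a disk.  Each body
    part's emissivity is jittered by at most `intensity_jitter` so frames are
    not perfectly flat; the background is exactly `background_intensity`.
    """
    if not 0.0 < body_intensity <= 1.0:
        raise ValueError("body_intensity must lie in (0, 1]")
    if background_intensity >= body_intensity:
        raise ValueError("body must be warmer than the background")
    kps = pose.keypoints
    l = pose.head_neck_length()
    if l < 1e-6:
        raise ValueError("degenerate pose: head-top and neck coincide")
    rng = np.random.default_rng(rng_seed)
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    body = np.zeros((height, width))

    def paint(cov):
        part = body_intensity * (1.0 - rng.uniform(0.0, intensity_jitter))
        np.maximum(body, cov * part, out=body)

    # head disk: centered between head-top and neck, biased toward the top
    head_center = kps[HEAD_TOP] + 0.38 * (kps[NECK] - kps[HEAD_TOP])
    paint(_capsule_coverage(yy, xx, head_center, head_center, 0.48 * l))
    mid_hip = 0.5 * (kps[2] + kps[3])
    paint(_capsule_coverage(yy, xx, kps[NECK], mid_hip, _TORSO_RADIUS))
    for edge in SKELETON_EDGES:
        paint(_capsule_coverage(yy, xx, kps[edge[0]], kps[edge[1]],
                                _EDGE_RADIUS[edge]))

    out = np.where(body > 0, np.maximum(body, background_intensity),
                   background_intensity)
    return IRFrame(np.clip(out, 0.0, 1.0), cover_state="none")


def save_frame(frame: IRFrame, path) -> None:
    """Store a frame as 8-bit grayscale PNG."""
    arr = np.round(frame.pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_frame(path, cover_state: str = "none") -> IRFrame:
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0
    return IRFrame(arr, cover_state=cover_state)


def _sample_family(rng) -> str:
    return POSE_FAMILIES[rng.choice(3, p=[0.5, 0.25, 0.25])]


def _make_covered(frame: IRFrame, factor: float, rng: np.random.Generator,
                  cover_state: str, roughness: float = 0.5) -> IRFrame:
    """Covered fixture frame: blanket from the neck/chest line downward.

    The blanket top sits at the upper-quarter boundary (head and shoulders
    stay uncovered, everything below is covered — the situation the
    attenuation estimator assumes) and the mask threshold sits just above
    the background so anti-aliased body edges are covered too.
    """
    wrinkle = augment.generate_wrinkle_map(frame.pixels.shape,
                                           int(rng.integers(2 ** 31)),
                                           roughness)
    mask = augment.body_mask(frame, 0.15)
    top = frame.height // 4
    covered = augment.synthesize_cover(frame, mask, factor, wrinkle,
                                       (top, frame.height))
    return IRFrame(covered.pixels, cover_state=cover_state)


def build_recovery_frames(true_factor: float, n: int, rng_seed: int):
    """Covered frames built for attenuation-factor recovery tests.

    Body intensity is uniform in the upper and lower regions (no emissivity
    jitter, flat cloth, no sensor noise) and the cover starts exactly at the
    upper-quarter boundary, so the ratio estimator should recover
    `true_factor` almost exactly.
    """
    rng = np.random.default_rng(rng_seed)
    frames = []
    for _ in range(n):
        pose = generate_subject_pose(int(rng.integers(2 ** 31)),
                                     _sample_family(rng))
        frame = render_frame(pose, int(rng.integers(2 ** 31)),
                             intensity_jitter=0.0)
        # low threshold: anti-aliased body edges must be covered too, or the
        # lower-region max would be an unattenuated edge pixel
        wrinkle = augment.WrinkleMap(np.ones(frame.pixels.shape))
        mask = augment.body_mask(frame, 0.15)
        covered = augment.synthesize_cover(
            frame, mask, true_factor, wrinkle,
            (frame.height // 4, frame.height))
        frames.append(IRFrame(covered.pixels, cover_state="thin"))
    return frames


def generate_eval_set(n: int, rng_seed: int, covered: bool = False,
                      factor_range=(0.35, 0.7), noise_sigma: float = 0.008):
    """In-memory (frame, pose) pairs for quick evaluations."""
    rng = np.random.default_rng(rng_seed)
    pairs = []
    for _ in range(n):
        pose = generate_subject_pose(int(rng.integers(2 ** 31)),
                                     _sample_family(rng))
        frame = render_frame(pose, int(rng.integers(2 ** 31)))
        if covered:
            factor = rng.uniform(*factor_range)
            frame = _make_covered(frame, factor, rng, "thin")
        if noise_sigma > 0:
            frame = augment.add_sensor_noise(frame, noise_sigma,
                                             int(rng.integers(2 ** 31)))
        pairs.append((frame, pose))
    return pairs


def build_manifest(n_uncovered: int, n_thin: int, n_thick: int,
                   n_val: int, n_test: int, rng_seed: int, out_dir,
                   thin_factor_range=(0.55, 0.75),
                   thick_factor_range=(0.3, 0.5),
                   noise_sigma: float = 0.008,
                   wrinkle_roughness: float = 0.5) -> DatasetManifest:
    """Write a synthetic dataset mirroring the structure of in-bed LWIR sets.

    Training: `n_uncovered` annotated uncovered frames plus `n_thin`/`n_thick`
    *unannotated* covered frames (their true attenuation factor is recorded
    in ``attenuation_truth.json`` for parameter-recovery tests).  Validation
    and test splits contain only covered, annotated frames, half thin and
    half thick.
    """
    for name, n in (("n_uncovered", n_uncovered), ("n_thin", n_thin),
                    ("n_thick", n_thick), ("n_val", n_val), ("n_test", n_test)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    out_dir = Path(out_dir)
    rng = np.random.default_rng(rng_seed)
    records, truth = [], {}
    total = n_uncovered + n_thin + n_thick + n_val + n_test
    if total > 0:
        (out_dir / "frames").mkdir(parents=True, exist_ok=True)
        (out_dir / "annotations").mkdir(parents=True, exist_ok=True)

    def emit(idx, frame, pose, cover, split, true_f=None):
        name = f"{split}_{cover}_{idx:04d}"
        rel = f"frames/{name}.png"
        if noise_sigma > 0:
            frame = augment.add_sensor_noise(frame, noise_sigma,
                                             int(rng.integers(2 ** 31)))
        save_frame(frame, out_dir / rel)
        kps = None if pose is None else [[float(x), float(y)]
                                         for x, y in pose.keypoints]
        rec = ManifestRecord(frame=rel, cover=cover, keypoints=kps, split=split)
        records.append(rec)
        with open(out_dir / "annotations" / f"{name}.json", "w") as fh:
            json.dump({"image": rel, "cover": cover, "keypoints": kps,
                       "split": split}, fh)
        if true_f is not None:
            truth[rel] = float(true_f)

    def fresh():
        pose = generate_subject_pose(int(rng.integers(2 ** 31)),
                                     _sample_family(rng))
        frame = render_frame(pose, int(rng.integers(2 ** 31)))
        return frame, pose

    for i in range(n_uncovered):
        frame, pose = fresh()
        emit(i, frame, pose, "none", "train")
    for cover, n, frange in (("thin", n_thin, thin_factor_range),
                             ("thick", n_thick, thick_factor_range)):
        for i in range(n):
            frame, pose = fresh()
            f = rng.uniform(*frange)
            emit(i, _make_covered(frame, f, rng, cover, wrinkle_roughness),
                 None, cover, "train", true_f=f)
    for split, n in (("val", n_val), ("test", n_test)):
        for i in range(n):
            frame, pose = fresh()
            cover = "thin" if i < (n + 1) // 2 else "thick"
            frange = thin_factor_range if cover == "thin" else thick_factor_range
            f = rng.uniform(*frange)
            emit(i, _make_covered(frame, f, rng, cover, wrinkle_roughness),
                 pose, cover, split, true_f=f)

    manifest = DatasetManifest(records=records, seed=int(rng_seed))
    if total > 0:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=1)
        with open(out_dir / "attenuation_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return manifest


def load_manifest(dataset_dir) -> DatasetManifest:
    with open(Path(dataset_dir) / "manifest.json") as fh:
        return DatasetManifest.from_dict(json.load(fh))


def load_records(manifest: DatasetManifest, dataset_dir, split=None,
                 cover=None):
    """Materialize (IRFrame, Pose | None) pairs for selected records."""
    out = []
    for rec in manifest.records:
        if split is not None and rec.split != split:
            continue
        if cover is not None and rec.cover != cover:
            continue
        frame = load_frame(Path(dataset_dir) / rec.frame, cover_state=rec.cover)
        out.append((frame, rec.pose(), rec))
    return out
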