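"""Core domain types shared across the package.

Coordinate convention (used everywhere): ``x`` is the column index, ``y`` is
the row index, both 0-based, with pixel centers at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_KEYPOINTS = 14

#: LSP-style 14-joint order.  The underlying dataset convention is
#: configurable via :func:`set_joint_order`, since annotation sources differ.
JOINT_NAMES = (
    "r_ankle", "r_knee", "r_hip", "l_hip", "l_knee", "l_ankle",
    "r_wrist", "r_elbow", "r_shoulder", "l_shoulder", "l_elbow", "l_wrist",
    "neck", "head_top",
)

#: Left/right mirror pairs (index_a, index_b) swapped on horizontal flip.
MIRROR_PAIRS = ((0, 5), (1, 4), (2, 3), (6, 11), (7, 10), (8, 9))

#: Skeleton edges used for rendering and limb-length checks.
SKELETON_EDGES = (
    (12, 8), (12, 9),            # neck -> shoulders
    (8, 7), (7, 6),              # right arm
    (9, 10), (10, 11),           # left arm
    (2, 3),                      # pelvis
    (2, 1), (1, 0),              # right leg
    (3, 4), (4, 5),              # left leg
)

#: Parent joint of each distal joint (used by limb-shrink deformations).
DISTAL_PARENTS = {6: 7, 11: 10, 0: 1, 5: 4}

NECK, HEAD_TOP = 12, 13

_JOINT_ORDER = {"names": JOINT_NAMES, "mirror_pairs": MIRROR_PAIRS}


def set_joint_order(names, mirror_pairs) -> None:
    """Override the keypoint naming/mirroring convention globally."""
    if len(names) != N_KEYPOINTS:
        raise ValueError(f"expected {N_KEYPOINTS} joint names")
    _JOINT_ORDER["names"] = tuple(names)
    _JOINT_ORDER["mirror_pairs"] = tuple(tuple(p) for p in mirror_pairs)


def get_mirror_pairs():
    return _JOINT_ORDER["mirror_pairs"]


COVER_STATES = ("none", "thin", "thick", "synthetic")


@dataclass
class IRFrame:
    """Single-channel LWIR-like intensity grid with a cover-provenance tag."""

    pixels: np.ndarray
    cover_state: str = "none"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("IRFrame.pixels must be a 2-D array")
        h, w = self.pixels.shape
        if h < 8 or w < 8:
            raise ValueError("frame must be at least 8x8 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("frame intensities must be finite")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("frame intensities must lie in [0, 1]")
        if self.cover_state not in COVER_STATES:
            raise ValueError(f"unknown cover_state {self.cover_state!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def copy(self, cover_state: str | None = None) -> "IRFrame":
        return IRFrame(self.pixels.copy(),
                       cover_state or self.cover_state)


@dataclass
class Pose:
    """Ordered set of 14 (x, y) keypoints in pixel coordinates.

    Coordinates may fall outside the frame only for deliberately deformed
    (negative-example) poses; invisible keypoints are NaN.
    """

    keypoints: np.ndarray

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=np.float64)
        if self.keypoints.shape != (N_KEYPOINTS, 2):
            raise ValueError(f"Pose requires shape ({N_KEYPOINTS}, 2)")
        if np.any(np.isinf(self.keypoints)):
            raise ValueError("keypoint coordinates must not be infinite")

    @property
    def visible(self) -> np.ndarray:
        return ~np.isnan(self.keypoints).any(axis=1)

    def head_neck_length(self) -> float:
        return float(np.linalg.norm(self.keypoints[HEAD_TOP]
                                    - self.keypoints[NECK]))

    def copy(self) -> "Pose":
        return Pose(self.keypoints.copy())


@dataclass
class ManifestRecord:
    frame: str                      # path relative to the dataset directory
    cover: str                      # none | thin | thick
    keypoints: list | None          # [[x, y] * 14] or None (unannotated)
    split: str                      # train | val | test

    def pose(self) -> Pose | None:
        return None if self.keypoints is None else Pose(np.asarray(self.keypoints))


@dataclass
class DatasetManifest:
    records: list = field(default_factory=list)
    seed: int = 0

    def __iter__(self):
        return iter(self.records)

    def split(self, name: str):
        return [r for r in self.records if r.split == name]

    def to_dict(self) -> dict:
        return {"seed": self.seed,
                "records": [vars(r).copy() for r in self.records]}

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetManifest":
        return cls(records=[ManifestRecord(**r) for r in d["records"]],
                   seed=int(d["seed"]))
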