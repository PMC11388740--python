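"""Run configuration: one structured object for all hyperparameters.

Defaults follow the published training recipe where one exists (priming with
AdamW at a constant 1e-3 for 25 epochs; adaptation with a one-cycle policy at
max 9e-4 for up to 100 epochs with early-stopping patience 10; target-Gaussian
radius shrinking 3 -> 1 over the first 30 epochs; pseudo-label acceptance
threshold tau = 0.7; refinement window d = 5 with N = 3 iterations).  The
``tiny()`` preset scales the schedule and model down to sizes that train in
minutes on one CPU; it changes capacity and duration, never the scheme.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import yaml

from .models import PoseNetConfig

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(global_seed: int, module_name: str) -> int:
    """Fan a single run seed out to per-module generators (stable hash)."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(module_name.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    seed: int = 0
    # model
    pose_net: PoseNetConfig = field(default_factory=PoseNetConfig)
    # augmentation probabilities (cover / noise / occlusion / flip)
    p_cover: float = 0.8
    p_noise: float = 0.5
    p_occlude: float = 0.3
    p_flip: float = 0.5
    noise_sigma: float = 0.02
    wrinkle_roughness: float = 0.5
    # schedules
    priming_epochs: int = 25
    priming_lr: float = 1e-3
    adapt_epochs: int = 100
    adapt_max_lr: float = 9e-4
    patience: int = 10
    batch_size: int = 8
    weight_decay: float = 1e-4
    # heatmap radius schedule
    radius_start: float = 3.0
    radius_end: float = 1.0
    radius_ramp_epochs: int = 30
    # semi-supervised loop
    tau: float = 0.7
    max_iterations: int = 3
    filter_policy: str = "discriminator"   # discriminator | random10 | all
    reinit_each_iteration: bool = True
    disc_epochs: int = 30
    disc_lr: float = 2e-3
    disc_input_size: int = 64
    # decoding
    refine_window: int = 5
    refine_iterations: int = 3

    @classmethod
    def tiny(cls, seed: int = 0) -> "RunConfig":
        """CPU-scale preset used by the test suite and worked examples."""
        return cls(
            seed=seed,
            pose_net=PoseNetConfig(input_size=48, heatmap_size=24,
                                   deconv_blocks=3, deconv_channels=24,
                                   base_width=8, seed=seed),
            priming_epochs=6,
            adapt_epochs=18,
            patience=6,
            radius_ramp_epochs=10,
            max_iterations=2,
            disc_epochs=30,
            disc_input_size=48,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "pose_net" in d and isinstance(d["pose_net"], dict):
            d["pose_net"] = PoseNetConfig(**d["pose_net"])
        return cls(**d)

    def save_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
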