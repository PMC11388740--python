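"""Pose-estimation network, pose discriminator, losses and deformations.

The pose network follows the simple-baselines recipe: a convolutional
encoder downsamples the (channel-replicated, nearest-upscaled) input frame,
a decoder of upsample-conv blocks brings the features back up, and a final
convolution with a per-channel spatial softmax emits one probability map per
keypoint.  The pose discriminator scores an (image, heatmap) pair between 0
and 1 via a pose-attention block: the heatmaps act as spatial attention
weights on mid-network features, are concatenated back for redundancy, and a
1x1 convolution restores the expected channel count.

Only a small CPU backbone is shipped; the architecture contract (not the
capacity) is what this package exercises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .core import (DISTAL_PARENTS, IRFrame, N_KEYPOINTS, Pose,
                   get_mirror_pairs)
from .heatmaps import HeatmapStack, encode_pose

__all__ = [
    "PoseNetConfig", "DiscriminatorScore", "build_pose_net",
    "build_pose_discriminator", "pose_loss", "discriminator_loss",
    "deform_heatmaps", "DEFORMATION_MODES", "frames_to_input",
    "save_checkpoint", "load_checkpoint", "train_pose_discriminator",
]

DEFORMATION_MODES = ("limb-shrink", "jitter", "lr-swap")


@dataclass
class PoseNetConfig:
    """Configuration of the heatmap pose network.

    ``deconv_channels`` defaults to 16 for the tiny CPU backbone; 256 is the
    width used with large pretrained backbones and remains configurable.
    """

    backbone_name: str = "tiny"
    input_size: int = 440
    heatmap_size: int = 114
    n_keypoints: int = N_KEYPOINTS
    deconv_blocks: int = 3
    deconv_channels: int = 16
    base_width: int = 8
    seed: int = 0

    def n_down(self) -> int:
        extra = int(round(np.log2(max(self.input_size / self.heatmap_size, 1.0))))
        return self.deconv_blocks + max(extra, 0)

    def validate(self):
        if self.backbone_name != "tiny":
            raise ValueError(f"unknown backbone {self.backbone_name!r}; "
                             "only the tiny test backbone is built in")
        if self.input_size < 2 ** self.n_down():
            raise ValueError("input_size incompatible with the required "
                             f"downsampling depth {self.n_down()}")
        if self.input_size < self.heatmap_size:
            raise ValueError("heatmap_size must not exceed input_size")
        if self.heatmap_size < 2 or self.input_size < 8:
            raise ValueError("sizes too small")
        return self


@dataclass
class DiscriminatorScore:
    score: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def _resize_nearest_np(arr: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = arr.shape[-2], arr.shape[-1]
    ri = np.minimum(np.arange(out_h) * h // out_h, h - 1)
    ci = np.minimum(np.arange(out_w) * w // out_w, w - 1)
    return arr[..., ri[:, None], ci[None, :]]


def frames_to_input(frames, input_size: int) -> np.ndarray:
    """Stack frames to a (N, 3, S, S) batch: nearest-neighbor upscale to the
    network input size and replicate the single LWIR channel three times."""
    if isinstance(frames, IRFrame):
        frames = [frames]
    batch = np.stack([_resize_nearest_np(f.pixels, input_size, input_size)
                      for f in frames])
    return np.repeat(batch[:, None], 3, axis=1)


class _ConvBNRelu(nn.Module):
    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class PoseNet(nn.Module):
    """Encoder-decoder heatmap network with per-channel spatial softmax."""

    def __init__(self, config: PoseNetConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths, w = [], config.base_width
        for _ in range(config.n_down()):
            widths.append(w)
            w = min(w * 2, config.base_width * 8)
        stages, cin = [], 3
        for cout in widths:
            stages.append(_ConvBNRelu(cin, cout, 2, rng))
            cin = cout
        self.encoder = nn.Sequential(*stages)
        blocks = []
        for _ in range(config.deconv_blocks):
            blocks.append(nn.UpsampleConvBlock(cin, config.deconv_channels, rng))
            cin = config.deconv_channels
        self.decoder = nn.Sequential(*blocks)
        self.head = nn.Conv2d(cin, config.n_keypoints, 3, rng=rng)

    def forward(self, x) -> nn.Tensor:
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        logits = self.head(self.decoder(self.encoder(x)))
        hm = self.config.heatmap_size
        logits = logits.resize_nearest(hm, hm)
        return logits.spatial_softmax()

    def predict(self, frames, flip_averaged: bool = False) -> list:
        """Inference to HeatmapStack objects (eval mode, no gradients)."""
        from .augment import hflip
        from .heatmaps import flip_average

        if isinstance(frames, IRFrame):
            frames = [frames]
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(frames_to_input(frames,
                                                   self.config.input_size)).data
                if flip_averaged:
                    flipped = [hflip(f)[0] for f in frames]
                    out_f = self.forward(
                        frames_to_input(flipped, self.config.input_size)).data
        finally:
            if was_training:
                self.train()
        hm = self.config.heatmap_size
        stacks = []
        for i, f in enumerate(frames):
            scale = (f.width / hm, f.height / hm)
            stack = HeatmapStack(out[i], scale=scale)
            if flip_averaged:
                stacks.append(flip_average(
                    stack, HeatmapStack(out_f[i], scale=scale)))
            else:
                stacks.append(stack)
        return stacks


def build_pose_net(config: PoseNetConfig | None = None) -> PoseNet:
    return PoseNet(config or PoseNetConfig())


class PoseDiscriminator(nn.Module):
    """Scores an (image, heatmap stack) pair for annotation plausibility."""

    def __init__(self, backbone_name: str = "tiny", input_size: int = 64,
                 base_width: int = 8, seed: int = 0):
        super().__init__()
        if backbone_name != "tiny":
            raise ValueError(f"unknown backbone {backbone_name!r}")
        self.input_size = input_size
        rng = np.random.default_rng(seed)
        w = base_width
        self.front = nn.Sequential(_ConvBNRelu(1, w, 2, rng),
                                   _ConvBNRelu(w, 2 * w, 2, rng))
        # pose-attention block: 1x1 conv maps (features + heatmaps) back to
        # the channel count the back half expects
        self.attn_proj = nn.Conv2d(2 * w + N_KEYPOINTS, 2 * w, 1, rng=rng)
        self.back = nn.Sequential(_ConvBNRelu(2 * w, 4 * w, 2, rng),
                                  _ConvBNRelu(4 * w, 4 * w, 2, rng))
        self.fc = nn.Linear(4 * w, 1, rng=rng)

    def forward(self, frames, heatmaps) -> nn.Tensor:
        if not isinstance(frames, nn.Tensor):
            frames = nn.Tensor(frames)
        if not isinstance(heatmaps, nn.Tensor):
            heatmaps = nn.Tensor(heatmaps)
        feats = self.front(frames)
        fh, fw = feats.shape[-2], feats.shape[-1]
        hm = heatmaps.resize_nearest(fh, fw)
        # spatial attention: channel-summed heatmaps, peak-normalized
        attn = hm.sum(axis=1, keepdims=True)
        peak = attn.data.max(axis=(-1, -2), keepdims=True)
        attn = attn * nn.Tensor(1.0 / np.maximum(peak, 1e-12))
        attended = feats * attn
        merged = self.attn_proj(nn.concat([attended, hm], axis=1))
        pooled = self.back(merged).mean(axis=(2, 3))
        return self.fc(pooled).sigmoid()

    def score(self, frame: IRFrame, stack: HeatmapStack) -> DiscriminatorScore:
        batch = _resize_nearest_np(frame.pixels, self.input_size,
                                   self.input_size)[None, None]
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                s = self.forward(batch, stack.maps[None]).data
        finally:
            if was_training:
                self.train()
        return DiscriminatorScore(float(s[0, 0]))


def build_pose_discriminator(backbone_name: str = "tiny",
                             **kwargs) -> PoseDiscriminator:
    return PoseDiscriminator(backbone_name=backbone_name, **kwargs)


def _stack_data(x):
    if isinstance(x, HeatmapStack):
        return x.maps
    if isinstance(x, nn.Tensor):
        return x
    return np.asarray(x, dtype=np.float64)


def pose_loss(predicted, target):
    """Sum over keypoint channels of the per-channel MSE.

    Accepts HeatmapStack / ndarray / Tensor, 3-D (K, H, W) or batched 4-D
    (N, K, H, W); batches average the per-channel MSE over samples.  Returns
    a Tensor when either input is one (for backprop), else a float.
    """
    p, t = _stack_data(predicted), _stack_data(target)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    axes = (1, 2) if p.ndim == 3 else (0, 2, 3)
    if isinstance(p, nn.Tensor) or isinstance(t, nn.Tensor):
        p = p if isinstance(p, nn.Tensor) else nn.Tensor(p)
        t = t if isinstance(t, nn.Tensor) else nn.Tensor(t)
        return ((p - t) ** 2.0).mean(axis=axes).sum()
    return float(((p - t) ** 2).mean(axis=axes).sum())


def discriminator_loss(score, label):
    """Binary cross-entropy with an epsilon clamp on the score."""
    eps = 1e-7
    label = float(label)
    if label not in (0.0, 1.0):
        raise ValueError("label must be 0 or 1")
    if isinstance(score, DiscriminatorScore):
        score = score.score
    if isinstance(score, nn.Tensor):
        s = score * (1.0 - 2.0 * eps) + eps  # smooth clamp, keeps gradients
        return -(label * s.log() + (1.0 - label) * (1.0 - s).log()).mean()
    s = min(max(float(score), eps), 1.0 - eps)
    return float(-(label * np.log(s) + (1.0 - label) * np.log(1.0 - s)))


def deform_heatmaps(pose: Pose, rng_seed: int, mode: str,
                    heatmap_shape=(40, 30), scale=4.0, radius: float = 2.0,
                    factor: float | None = None):
    """Produce a corrupted pose and its heatmap encoding (negative example).

    ``limb-shrink`` pulls wrists/ankles toward their parent joints by a
    factor in [0.3, 0.7] (mimicking the abnormally-small-limb failure mode of
    bad pseudo-annotations); ``jitter`` displaces a random subset of joints
    by at least twice the PCKh@0.5 tolerance (i.e. at least the head-neck
    length); ``lr-swap`` exchanges the left/right mirror pairs.
    """
    if mode not in DEFORMATION_MODES:
        raise ValueError(f"unknown deformation mode {mode!r}")
    rng = np.random.default_rng(rng_seed)
    kps = pose.keypoints.copy()
    if mode == "limb-shrink":
        for distal, parent in DISTAL_PARENTS.items():
            f = factor if factor is not None else rng.uniform(0.3, 0.7)
            kps[distal] = kps[parent] + f * (kps[distal] - kps[parent])
    elif mode == "jitter":
        l = pose.head_neck_length()
        chosen = rng.random(N_KEYPOINTS) < 0.5
        if not chosen.any():
            chosen[rng.integers(N_KEYPOINTS)] = True
        for i in np.flatnonzero(chosen):
            ang = rng.uniform(0, 2 * np.pi)
            mag = rng.uniform(1.0, 2.0) * l  # >= 2 * (0.5 * l)
            kps[i] += mag * np.array([np.cos(ang), np.sin(ang)])
    else:  # lr-swap
        for a, b in get_mirror_pairs():
            kps[[a, b]] = kps[[b, a]]
    deformed = Pose(kps)
    stack = encode_pose(deformed, heatmap_shape, scale, radius)
    return deformed, stack


def train_pose_discriminator(samples, disc: PoseDiscriminator | None = None,
                             epochs: int = 30, batch_size: int = 8,
                             lr: float = 2e-3, rng_seed: int = 0,
                             heatmap_shape=(40, 30), scale=4.0,
                             radius: float = 2.0):
    """Train a pose discriminator on (frame, pose) pairs.

    Positives are ground-truth heatmap encodings; negatives are deformations
    (limb-shrink / jitter / lr-swap, cycled).  Returns (model, history) with
    per-epoch mean BCE loss.
    """
    disc = disc or build_pose_discriminator(seed=rng_seed)
    rng = np.random.default_rng(rng_seed)
    inputs, hms, labels = [], [], []
    for i, (frame, pose) in enumerate(samples):
        img = _resize_nearest_np(frame.pixels, disc.input_size,
                                 disc.input_size)[None]
        gt = encode_pose(pose, heatmap_shape, scale, radius)
        inputs.append(img)
        hms.append(gt.maps)
        labels.append(1.0)
        mode = DEFORMATION_MODES[i % len(DEFORMATION_MODES)]
        _, bad = deform_heatmaps(pose, int(rng.integers(2 ** 31)), mode,
                                 heatmap_shape, scale, radius)
        inputs.append(img)
        hms.append(bad.maps)
        labels.append(0.0)
    inputs = np.asarray(inputs)
    hms = np.asarray(hms)
    labels = np.asarray(labels)
    opt = nn.AdamW(disc.parameters(), lr=lr)
    history = []
    n = len(labels)
    disc.train()
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            scores = disc(inputs[idx], hms[idx])
            y = labels[idx][:, None]
            eps = 1e-7
            s = scores * (1.0 - 2 * eps) + eps
            loss = -(nn.Tensor(y) * s.log()
                     + nn.Tensor(1.0 - y) * (1.0 - s).log()).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    disc.eval()
    return disc, history


def save_checkpoint(model: nn.Module, path, metadata: dict | None = None):
    """Model weights as npz plus a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(path, **model.state_dict())
    meta = dict(metadata or {})
    if hasattr(model, "config") and isinstance(model.config, PoseNetConfig):
        meta["config"] = asdict(model.config)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_checkpoint(path, model: nn.Module | None = None):
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    if model is None:
        model = build_pose_net(PoseNetConfig(**meta["config"]))
    state = dict(np.load(path))
    model.load_state_dict(state)
    return model, meta
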