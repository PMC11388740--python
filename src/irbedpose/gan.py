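"""Style-transfer GAN that "paints" a blanket onto uncovered frames.

The generator receives an uncovered frame Xu, a covered style reference Xc
and a uniform noise vector in [-0.5, 0.5]; the noise is linearly transformed
and reshaped into an Xu-shaped map, concatenated with Xu and encoded; the
style branch encodes Xc with a 7x7 convolution followed by parallel 5x5
stride-1 average and max pooling (a coarse summary of the reference's
intensity distribution).  The merged trunk is an inception block, a 3x3
convolution, five residual blocks and two more 3x3 convolutions; every
convolution except the output one is followed by batch normalization and
SELU, all stride 1 with shape-preserving padding.

The discriminator is an initial 3x3 convolution, an inception block and six
3x3 convolutions producing a score map one-sixteenth the input size (all
ones = real covered, all zeros = synthetic).  Since 120 is not divisible by
16, 160x120 frames are reflect-padded to 160x128 before discrimination.

This augmentation path is optional and excluded from the default training
pipeline: statistically augmented data trains more accurate pose models than
GAN-synthesized data, so the GAN exists for completeness and comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .core import IRFrame

__all__ = [
    "GanBatch", "build_generator", "build_gan_discriminator",
    "generator_loss", "gan_discriminator_loss", "train_gan",
    "pad_for_discriminator", "NOISE_DIM",
]

NOISE_DIM = 64


@dataclass
class GanBatch:
    uncovered: IRFrame
    style_reference: IRFrame
    noise_vector: np.ndarray
    synthetic: IRFrame | None = None

    def __post_init__(self):
        self.noise_vector = np.asarray(self.noise_vector, dtype=np.float64)
        if self.noise_vector.min() < -0.5 or self.noise_vector.max() > 0.5:
            raise ValueError("noise entries must lie in [-0.5, 0.5]")


def sample_noise(rng: np.random.Generator, n: int = 1,
                 dim: int = NOISE_DIM) -> np.ndarray:
    return rng.uniform(-0.5, 0.5, size=(n, dim))


def pad_for_discriminator(pixels: np.ndarray) -> np.ndarray:
    """Reflect-pad the last two axes up to the next multiple of 16."""
    h, w = pixels.shape[-2], pixels.shape[-1]
    ph, pw = (-h) % 16, (-w) % 16
    if ph == 0 and pw == 0:
        return pixels
    width = [(0, 0)] * (pixels.ndim - 2) + \
        [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)]
    return np.pad(pixels, width, mode="reflect")


class _ConvBNSelu(nn.Module):
    def __init__(self, cin, cout, kernel, rng, stride=1):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, kernel, stride=stride,
                              padding=kernel // 2, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).selu()


class Generator(nn.Module):
    def __init__(self, width_multiplier: float = 1.0, noise_dim: int = NOISE_DIM,
                 frame_shape=(160, 120), seed: int = 0):
        super().__init__()
        if width_multiplier <= 0:
            raise ValueError("width_multiplier must be > 0")
        rng = np.random.default_rng(seed)
        w = max(int(round(32 * width_multiplier)), 2)
        self.frame_shape = tuple(frame_shape)
        self.noise_dim = noise_dim
        h, wd = self.frame_shape
        self.noise_fc = nn.Linear(noise_dim, h * wd, rng=rng)
        self.content_enc = _ConvBNSelu(2, w, 3, rng)       # (Xu, N) -> features
        self.style_enc = _ConvBNSelu(1, w, 7, rng)         # Xc -> 7x7 conv
        # avg+max pooled style branches concatenate to 2w channels
        self.inception = nn.InceptionBlock(3 * w, w, rng)
        self.mid = _ConvBNSelu(w, w, 3, rng)
        self.res = nn.Sequential(*[nn.ResidualBlock(w, rng) for _ in range(5)])
        self.penult = _ConvBNSelu(w, w, 3, rng)
        self.out = nn.Conv2d(w, 1, 3, rng=rng)

    def forward(self, xu, xc, noise) -> nn.Tensor:
        """(N,1,H,W) uncovered, (N,1,H,W) style reference, (N,noise_dim)."""
        if not isinstance(xu, nn.Tensor):
            xu = nn.Tensor(xu)
        if not isinstance(xc, nn.Tensor):
            xc = nn.Tensor(xc)
        if not isinstance(noise, nn.Tensor):
            noise = nn.Tensor(noise)
        if xu.shape != xc.shape:
            raise ValueError("Xu and Xc batches must share a shape")
        n = xu.shape[0]
        h, wd = xu.shape[-2], xu.shape[-1]
        nmap = self.noise_fc(noise).reshape(n, 1, h, wd)
        content = self.content_enc(nn.concat([xu, nmap], axis=1))
        style = self.style_enc(xc)
        s = nn.concat([style.avg_pool2d(5, stride=1, padding=2),
                       style.max_pool2d(5, stride=1, padding=2)], axis=1)
        trunk = self.inception(nn.concat([content, s], axis=1))
        trunk = self.res(self.mid(trunk))
        # no activation on the output layer; intensities are clipped to
        # [0, 1] only when materializing an IRFrame
        return self.out(self.penult(trunk))

    def synthesize(self, xu: IRFrame, xc: IRFrame,
                   rng_seed: int) -> IRFrame:
        rng = np.random.default_rng(rng_seed)
        noise = sample_noise(rng, 1, self.noise_dim)
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(xu.pixels[None, None],
                                   xc.pixels[None, None], noise).data
        finally:
            if was_training:
                self.train()
        return IRFrame(np.clip(out[0, 0], 0.0, 1.0), cover_state="synthetic")


class GanDiscriminator(nn.Module):
    """3x3 conv + inception + six 3x3 convs -> (H/16, W/16) score map."""

    def __init__(self, width_multiplier: float = 1.0, seed: int = 0):
        super().__init__()
        if width_multiplier <= 0:
            raise ValueError("width_multiplier must be > 0")
        rng = np.random.default_rng(seed)
        w = max(int(round(32 * width_multiplier)), 2)
        self.stem = _ConvBNSelu(1, w, 3, rng)
        self.inception = nn.InceptionBlock(w, w, rng)
        # four of the six 3x3 convs downsample: 2^4 = 16
        self.c1 = _ConvBNSelu(w, w, 3, rng, stride=2)
        self.c2 = _ConvBNSelu(w, 2 * w, 3, rng, stride=2)
        self.c3 = _ConvBNSelu(2 * w, 2 * w, 3, rng, stride=2)
        self.c4 = _ConvBNSelu(2 * w, 2 * w, 3, rng, stride=2)
        self.c5 = _ConvBNSelu(2 * w, 2 * w, 3, rng)
        self.out = nn.Conv2d(2 * w, 1, 3, rng=rng)

    def forward(self, x) -> nn.Tensor:
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        h, w = x.shape[-2], x.shape[-1]
        if h % 16 or w % 16:
            raise ValueError(
                f"input {h}x{w} not divisible by 16; pad first "
                "(see pad_for_discriminator)")
        y = self.inception(self.stem(x))
        y = self.c5(self.c4(self.c3(self.c2(self.c1(y)))))
        return self.out(y)


def build_generator(width_multiplier: float = 1.0, **kwargs) -> Generator:
    return Generator(width_multiplier=width_multiplier, **kwargs)


def build_gan_discriminator(width_multiplier: float = 1.0,
                            **kwargs) -> GanDiscriminator:
    return GanDiscriminator(width_multiplier=width_multiplier, **kwargs)


def _mse(a, b):
    d = a - b
    return (d * d).mean() if isinstance(d, nn.Tensor) else float(np.mean(d * d))


def generator_loss(xs, xu, xc, discriminator_output=None):
    """Composite generator loss; returns (total, components dict).

    g1 = MSE(D(Xs), 1)  — fool the discriminator (omitted if D output None);
    g2 = MSE(Xs, Xu * mean(Xc) / mean(Xu)) — preserve the pose;
    g3 = MSE(mean(Xs), mean(Xc)) and g4 = MSE(std(Xs), std(Xc)) — match the
    reference intensity distribution.  Means/stds pool all pixels per batch.
    """
    xs_t = xs if isinstance(xs, nn.Tensor) else nn.Tensor(np.asarray(xs, float))
    xu_d = xu.data if isinstance(xu, nn.Tensor) else np.asarray(xu, float)
    xc_d = xc.data if isinstance(xc, nn.Tensor) else np.asarray(xc, float)
    batched = xs_t.ndim == 4
    pix_axes = (1, 2, 3) if batched else None
    mean_xu = xu_d.mean(axis=pix_axes, keepdims=True) if batched \
        else np.asarray(xu_d.mean())
    if np.any(mean_xu == 0.0):
        raise ValueError("mean(Xu) is zero; cannot scale the pose target")
    mean_xc = xc_d.mean(axis=pix_axes, keepdims=True) if batched \
        else np.asarray(xc_d.mean())
    std_xc = xc_d.std(axis=pix_axes, keepdims=True) if batched \
        else np.asarray(xc_d.std())
    comps = {}
    comps["g2"] = _mse(xs_t, nn.Tensor(xu_d * (mean_xc / mean_xu)))
    if batched:
        # per-frame moments: all pixels of each frame pool to one value
        mu = xs_t.mean(axis=pix_axes, keepdims=True)
        var = ((xs_t - mu) ** 2.0).mean(axis=pix_axes, keepdims=True)
        sd = (var + 1e-12) ** 0.5
        comps["g3"] = ((mu - nn.Tensor(mean_xc)) ** 2.0).mean()
        comps["g4"] = ((sd - nn.Tensor(std_xc)) ** 2.0).mean()
    else:
        comps["g3"] = (xs_t.mean() - float(mean_xc)) ** 2.0
        comps["g4"] = (xs_t.std() - float(std_xc)) ** 2.0
    total = comps["g2"] + comps["g3"] + comps["g4"]
    if discriminator_output is not None:
        d = discriminator_output if isinstance(discriminator_output, nn.Tensor) \
            else nn.Tensor(np.asarray(discriminator_output, float))
        comps["g1"] = _mse(d, nn.Tensor(np.ones(d.shape)))
        total = comps["g1"] + total
    return total, comps


def gan_discriminator_loss(output_on_real, output_on_synthetic):
    """LD = 0.5 * (MSE(D(Xc), 1) + MSE(D(Xs), 0))."""
    r = output_on_real if isinstance(output_on_real, nn.Tensor) \
        else nn.Tensor(np.asarray(output_on_real, float))
    s = output_on_synthetic if isinstance(output_on_synthetic, nn.Tensor) \
        else nn.Tensor(np.asarray(output_on_synthetic, float))
    if r.shape != s.shape:
        raise ValueError("score map shapes must match")
    d1 = _mse(r, nn.Tensor(np.ones(r.shape)))
    d2 = (s * s).mean()
    return (d1 + d2) * 0.5


def train_gan(uncovered, covered, width_multiplier: float = 0.25,
              warmup_epochs: int = 10, adversarial_epochs: int = 10,
              lr: float = 1e-3, lr_decay: float = 0.9, batch_size: int = 4,
              rng_seed: int = 0, frame_shape=None):
    """Two-phase GAN training on random (Xu, Xc) pairs.

    Phase A trains the generator alone on LG minus the adversarial g1 term;
    phase B alternates generator and discriminator updates on the full
    losses.  Both optimizers are AdamW starting at `lr`, decayed by
    `lr_decay` each epoch.  Returns (generator, discriminator, history);
    history logs every loss component per epoch.
    """
    uncovered, covered = list(uncovered), list(covered)
    if not covered:
        raise ValueError("no covered frames to learn a style from")
    if not uncovered:
        raise ValueError("no uncovered frames to synthesize from")
    rng = np.random.default_rng(rng_seed)
    shape = frame_shape or uncovered[0].pixels.shape
    gen = Generator(width_multiplier, frame_shape=shape,
                    seed=int(rng.integers(2 ** 31)))
    disc = GanDiscriminator(width_multiplier, seed=int(rng.integers(2 ** 31)))
    g_opt = nn.AdamW(gen.parameters(), lr=lr)
    d_opt = nn.AdamW(disc.parameters(), lr=lr)
    g_sched = nn.ExponentialLR(g_opt, lr_decay)
    d_sched = nn.ExponentialLR(d_opt, lr_decay)

    xu_all = np.stack([f.pixels for f in uncovered])[:, None]
    xc_all = np.stack([f.pixels for f in covered])[:, None]
    history = []

    def batches():
        iu = rng.permutation(len(uncovered))
        for lo in range(0, len(iu), batch_size):
            sel = iu[lo:lo + batch_size]
            ic = rng.integers(0, len(covered), size=len(sel))
            yield xu_all[sel], xc_all[ic]

    total_epochs = warmup_epochs + adversarial_epochs
    for epoch in range(total_epochs):
        adversarial = epoch >= warmup_epochs
        logs = {"epoch": epoch, "phase": "B" if adversarial else "A",
                "lr": g_opt.lr}
        sums, count = {}, 0
        for xu, xc in batches():
            noise = sample_noise(rng, len(xu), gen.noise_dim)
            gen.train()
            xs = gen(xu, xc, noise)
            d_out = None
            if adversarial:
                disc.eval()  # frozen BN stats while scoring for the generator
                ph, pw = _pad_amount(xs.shape)
                xs_p = xs.pad2d(ph // 2, pw // 2, mode="reflect") \
                    if (ph or pw) else xs
                d_out = disc(xs_p)
            g_total, comps = generator_loss(xs, xu, xc, d_out)
            g_opt.zero_grad()
            g_total.backward()
            g_opt.step()
            if adversarial:
                disc.train()
                with nn.no_grad():
                    xs_detached = gen(xu, xc, noise).data
                d_real = disc(nn.Tensor(pad_for_discriminator(xc)))
                d_fake = disc(nn.Tensor(pad_for_discriminator(xs_detached)))
                d_loss = gan_discriminator_loss(d_real, d_fake)
                d_opt.zero_grad()
                d_loss.backward()
                d_opt.step()
                comps["d"] = d_loss
            for k, v in comps.items():
                val = v.item() if isinstance(v, nn.Tensor) else float(v)
                sums[k] = sums.get(k, 0.0) + val
            count += 1
        logs.update({k: v / count for k, v in sums.items()})
        history.append(logs)
        g_sched.step()
        d_sched.step()
    gen.eval()
    disc.eval()
    return gen, disc, history


def _pad_amount(shape):
    h, w = shape[-2], shape[-1]
    ph, pw = (-h) % 16, (-w) % 16
    if ph % 2 or pw % 2:
        raise ValueError("frame shape requires asymmetric padding; "
                         "use even dimensions")
    return ph, pw
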