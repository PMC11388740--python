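# Methods

## Problem and model

The task is 2D keypoint estimation for a single person lying in bed, observed
by a long-wavelength infrared camera at 160×120 resolution. Fourteen
LSP-style joints are predicted ([R ankle, R knee, R hip, L hip, L knee,
L ankle, R wrist, R elbow, R shoulder, L shoulder, L elbow, L wrist, neck,
head-top]; the order and the left/right mirror pairs are configurable via
`irbedpose.core.set_joint_order`, since annotation conventions vary between
datasets). Coordinates are (x = column, y = row), 0-based, pixel centers at
integers.

The estimator is detection-based: the network emits one score map per joint
and the joint location is read off the map. The pose network is an
encoder–decoder. The encoder is a stack of stride-2 conv–BN–ReLU stages; the
decoder is a series of "deconvolution blocks", each realized as nearest 2×
upsampling followed by a 3×3 conv–BN–ReLU. Upsample-plus-conv plays the same
decoding role as a strided transposed convolution while avoiding checkerboard
artifacts and keeping the backward pass simple. A final 3×3 convolution maps
to 14 channels, the logits are nearest-resized to the configured heatmap
size, and a per-channel spatial softmax makes each map a probability
distribution over locations. Input frames are replicated to three channels
and nearest-upscaled to a square network input.

Only a tiny CPU backbone ships with the package. The network contract — not
its capacity — is what the test suite exercises; large pretrained backbones
would slot in behind `PoseNetConfig.backbone_name` but require a model zoo
this package deliberately does not depend on.

## Statistical cover augmentation

A blanket attenuates emitted IR roughly as `I = I0·exp(−α·x)`. Fabric α and
thickness x are unobservable separately, so only the factor
`F = exp(−α·x) ∈ (0, 1]` is estimated, per covered frame, as the ratio of the
maximum intensity in the lower three-fourths of the frame (covered body) to
the maximum in the upper fourth (uncovered head/shoulders). Assumptions:
the head region is uncovered, and the unattenuated body is roughly
isothermal so both maxima proxy the same skin intensity. Estimates above 1
contradict the first assumption and are discarded rather than clipped;
frames with an all-zero upper region are skipped with a warning.

Synthetic covers multiply body-mask pixels inside a row band by
`F_eff = F·(w_floor + (1 − w_floor)·W)`, where `W ∈ [1 − roughness/2, 1]` is
a band-limited random wrinkle field (Gaussian-filtered white noise,
correlation length 8 px) standing in for rendered cloth folds — darker folds
attenuate more. The blend floor `w_floor = 0.5` keeps the modulation
monotone and bounded; the linear-blend form is a design choice, as is the
cover band sampling law (top row uniform in [0.25·H, 0.6·H], extending to
the bottom; never above the upper-quarter line). One `F` is sampled per
synthesized image from the estimated bank.

On-the-fly augmentation compounds, per sample and independently: synthetic
cover (p = 0.8), Gaussian sensor noise (p = 0.5, σ = 0.02), heavy
rectangular occlusion (p = 0.3, ≤ 4 % of the frame area, ×0.1 attenuation),
and horizontal flip (p = 0.5, mirror-pair keypoint slots swapped). The
probabilities are package defaults; the compounding scheme, not the exact
probabilities, is the load-bearing choice.

## Heatmap encoding and decoding

Targets are isotropic Gaussians with σ = radius/2 truncated at 3σ, so the
kernel support approximately matches the nominal radius. The radius shrinks
linearly from 3 px to 1 px over the first 30 epochs (scaled runs shrink over
10): diffuse targets first guide the network to coarse locations, sharp ones
then pinpoint them. Channels are normalized to unit sum by default, making
them commensurate with the spatial-softmax output; a peak-1 mode exists for
raw-MSE training on unnormalized maps. Keypoints mapping outside the heatmap
produce an all-zero channel and are treated as invisible.

Decoding per channel: integer argmax (ties broken row-major, first
occurrence — a determinism choice), then N = 3 iterations of the windowed
center of mass: round the current estimate to the nearest pixel
(⌊v + 0.5⌋), take the d×d window (d = 5, half-width (d−1)/2 = 2,
out-of-bounds pixels contribute zero), move to the intensity-weighted
centroid. Zero window mass returns the seed flagged unconverged. The test
suite checks this implementation bitwise against an independent literal-loop
transcription of the same procedure. At inference, heatmaps from the frame
and its horizontal mirror are averaged after flipping the mirror's maps back
and swapping left/right channels — without the channel swap the operation
would not be an involution, since a mirrored image's "left wrist" channel
describes the anatomical right wrist.

## Two-phase semi-supervised training

Phase 1 (priming) trains on whatever annotated pose data is supplied; when
none is, the annotated uncovered fixtures serve (AdamW, constant lr 1e-3,
25 epochs at full scale). Phase 2 (adaptation) uses a one-cycle policy with
max lr 9e-4, up to 100 epochs, early-stopping patience 10 (scaled presets:
6 / 18–35 / 6–12), selecting checkpoints by validation AUC% rather than
loss. Each semi-supervised iteration: pseudo-label all unannotated covered
frames with flip-averaged inference, score each (frame, heatmaps) pair with
the pose discriminator, keep scores strictly above τ = 0.7, decode the kept
stacks to poses and add them to the training pool, then re-run training
(re-initialization each iteration is the default; fine-tuning is available).
All covered frames are re-labeled and re-scored each iteration, so earlier
selections are effectively re-validated. The loop stops when validation AUC%
fails to improve between iterations or after `max_iterations` (default 3).
`random10` and `select-all` filter policies are provided as ablation
baselines. Selected pseudo-label stacks are decoded to poses and re-encoded
with the scheduled radius during training — equivalent information to
training on the stacks directly, and it lets the geometric augmentations
(flip) apply uniformly.

The pose discriminator is a small CNN taking the frame and the heatmap
stack. After the second conv stage, the channel-summed, peak-normalized
heatmaps multiply the features as spatial attention; the heatmap channels
are concatenated back for redundancy and a 1×1 convolution restores the
channel count (attention insertion mid-network and nearest-neighbor heatmap
resizing are design choices; the published description leaves both open).
Global average pooling, a linear layer and a sigmoid give a score in [0, 1],
trained with binary cross-entropy: positives are ground-truth encodings,
negatives are deformations — limb-shrink (wrists/ankles pulled toward their
parent joint by a factor in [0.3, 0.7], the characteristic failure mode of
bad pseudo-labels), jitter (random joints displaced by at least twice the
PCKh@0.5 tolerance), and left/right swap. Inside the training loop the
discriminator is trained on *augmented* (incl. synthetically covered)
frames so its scores transfer to the covered domain it must judge.

## Cover-synthesis GAN

The generator encodes the uncovered frame concatenated with a noise map (a
64-entry uniform [−0.5, 0.5] vector through a linear layer, reshaped to the
frame shape), summarizes the covered style reference with a 7×7 convolution
followed by parallel 5×5 stride-1 average and max pooling, and merges both
through an inception block (classic 1×1 / 3×3 / 5×5 / pooled-1×1 form), a
3×3 conv, five residual blocks and two more 3×3 convs — all stride 1,
shape-preserving padding, BN + SELU everywhere except the output layer,
which is linear (intensities are clipped to [0, 1] only when materializing a
frame). The discriminator is a 3×3 conv, an inception block and six 3×3
convs of which four have stride 2, giving a score map one-sixteenth the
input size; 160×120 frames are reflect-padded to 160×128 first, since 120 is
not divisible by 16. Losses follow the composite form: `g1` adversarial MSE
against an all-ones map, `g2` pose preservation against the mean-ratio-scaled
uncovered frame, `g3`/`g4` mean/std matching (moments pooled over all pixels
of each frame). Training: generator alone on `L_G − g1` for 10 epochs, then
alternating updates for 10 more; AdamW, lr 1e-3 decayed ×0.9 per epoch. The
GAN is excluded from the default training path: synthetic covers from the
statistical route train more accurate pose models, so the GAN exists for
comparison.

## Synthetic fixtures: what they do and do not show

The generator emulates the structure of in-bed LWIR datasets: a warm body
(anti-aliased capsule limbs, disk head, per-part emissivity jitter ≤ 2 %) on
a uniform cool background; supine and side-lying joint-angle families;
uncovered annotated training frames, unannotated covered training frames,
covered annotated validation/test frames (mirroring the 30/25/25 subject
split structure at reduced scale); covers applied from the neck line down
with known factors recorded in a sidecar. Head-top and neck always land in
the upper quarter, matching the attenuation estimator's assumption.

Not emulated: realistic thermal texture and drift, anatomical appearance,
bedding geometry, camera noise beyond additive Gaussian, multi-person
scenes, or the visual complexity of real fabric. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that its orderings
(augmentation helps covered-domain accuracy; the discriminator separates
plausible from deformed annotations) hold under controlled conditions — not
that any particular accuracy level transfers to real recordings.

## Numerical and scale choices

- All array math is float64; models are small enough that robustness beats
  single-precision speed. The network toolkit is a minimal reverse-mode
  autograd over numpy (im2col convolutions, scatter-add backward passes),
  finite-difference-checked in the test suite.
- The tiny preset (`RunConfig.tiny()`) trains a 48×48-input, 24×24-heatmap
  network on ~80 annotated frames in tens of seconds per run on one CPU;
  the default `PoseNetConfig` (440 input, 114 heatmaps, 16-channel decoder)
  keeps a single-frame forward pass under a second. The 256-channel decoder
  width used with large backbones remains available via config.
- Default decoder logits are nearest-resized to the configured heatmap size,
  decoupling heatmap resolution from the 2^k geometry of the decoder.
- PCKh pools keypoints across images by default (per-image averaging is
  available); correctness is inclusive (error ≤ t·l); l always comes from
  ground truth. The AUC integration grid is t = 0, 0.01, …, 0.5 (51 points),
  fine enough that trapezoidal error is negligible for step-like curves at
  the dataset sizes used.
- Seeds: one run seed fans out to per-module generators via
  `derive_seed(seed, module_name)` (a CRC-based hash, always < 2^31), so any
  two runs with identical config and seed produce identical outputs.

## Known limitations

- The attenuation estimator inherits the head-uncovered assumption; frames
  violating it yield F ≈ 1 (or > 1, discarded), biasing the bank upward.
- The horizontal-flip coordinate map `(w−1) − x` is involutive only up to
  one floating-point rounding of the mirror (~1e-13 px at this resolution).
- The GAN's `g4` term carries a 1e-12 epsilon inside the differentiable
  standard deviation, so the "perfect generator" loss is ~1e-12, not 0.
- Training-ordering checks are stochastic and seed-pinned; they assert
  directions, not magnitudes.
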