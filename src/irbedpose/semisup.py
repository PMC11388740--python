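"""Two-phase semi-supervised training with discriminator-filtered pseudo-labels.

Phase 1 ("priming") trains the pose network on whatever annotated pose data
is available up front.  Phase 2 ("adaptation") iterates: train on annotated
uncovered frames with on-the-fly statistical cover augmentation (plus any
previously accepted pseudo-labeled covered frames), pick the checkpoint with
the best validation AUC%, pseudo-label the unannotated covered frames with
flip-averaged inference, score each (frame, heatmaps) pair with the pose
discriminator, keep those scoring strictly above tau, and repeat until the
validation score stops improving or the iteration budget is exhausted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .augment import AugmentationPipeline, estimate_attenuation_factors
from .config import RunConfig, derive_seed
from .heatmaps import (RefinementParams, decode_pose, encode_pose,
                       radius_at_epoch)
from .metrics import evaluate_poses
from .models import (PoseNet, build_pose_discriminator, build_pose_net,
                     frames_to_input, pose_loss, train_pose_discriminator)

__all__ = ["PseudoLabelBatch", "pseudo_label", "filter_pseudo_labels",
           "train_supervised", "run_training"]


@dataclass
class PseudoLabelBatch:
    """Scored pseudo-annotations for one semi-supervised iteration."""

    items: list = field(default_factory=list)  # (frame_ref, HeatmapStack, score)
    iteration: int = 0
    tau: float = 0.7

    def __post_init__(self):
        for _, _, s in self.items:
            if not 0.0 <= s <= 1.0:
                raise ValueError("scores must lie in [0, 1]")


def pseudo_label(model: PoseNet, frames) -> list:
    """Annotation heatmaps for unannotated frames (flip-averaged inference)."""
    frames = list(frames)
    if not frames:
        return []
    return model.predict(frames, flip_averaged=True)


def filter_pseudo_labels(batch: PseudoLabelBatch, policy: str = "discriminator",
                         rng: np.random.Generator | None = None) -> list:
    """Select pseudo-labels according to the filtering policy.

    ``discriminator`` keeps exactly the items with score strictly greater
    than tau (a score equal to tau is excluded).  ``random10`` keeps a random
    10% regardless of score and ``all`` keeps everything; both exist as the
    ablation baselines.
    """
    if policy == "discriminator":
        return [item for item in batch.items if item[2] > batch.tau]
    if policy == "all":
        return list(batch.items)
    if policy == "random10":
        rng = rng or np.random.default_rng(0)
        n = len(batch.items)
        k = max(int(round(0.1 * n)), 1) if n else 0
        idx = rng.choice(n, size=k, replace=False) if n else []
        return [batch.items[i] for i in idx]
    raise ValueError(f"unknown filter policy {policy!r}")


def _validation_auc(model: PoseNet, val_pairs, config: RunConfig,
                    flip_averaged: bool = False) -> float:
    params = RefinementParams(config.refine_window, config.refine_iterations)
    frames = [f for f, _ in val_pairs]
    gts = [p for _, p in val_pairs]
    stacks = model.predict(frames, flip_averaged=flip_averaged)
    preds = [decode_pose(s, params) for s in stacks]
    return evaluate_poses(preds, gts)["AUC%"]


def train_supervised(model: PoseNet, train_pairs, val_pairs,
                     config: RunConfig, rng: np.random.Generator,
                     pipeline: AugmentationPipeline | None = None,
                     epochs: int | None = None, one_cycle: bool = True,
                     lr: float | None = None):
    """Train on (frame, pose) pairs; returns (best_val_auc, epoch_history).

    The model is left holding the weights of the checkpoint with the best
    validation AUC%.  Targets are Gaussian heatmaps whose radius follows the
    shrinking schedule; augmentation (if any) is applied on the fly per
    sample, re-encoding targets after every geometric change.
    """
    if not train_pairs:
        raise ValueError("no annotated training data")
    epochs = epochs if epochs is not None else config.adapt_epochs
    hm = model.config.heatmap_size
    n = len(train_pairs)
    steps_per_epoch = max((n + config.batch_size - 1) // config.batch_size, 1)
    opt = nn.AdamW(model.parameters(), lr=lr or config.priming_lr,
                   weight_decay=config.weight_decay)
    sched = nn.OneCycleLR(opt, max_lr=config.adapt_max_lr,
                          total_steps=epochs * steps_per_epoch) \
        if one_cycle else None
    best_auc, best_state, since_best = -1.0, model.state_dict(), 0
    history = []
    for epoch in range(epochs):
        radius = radius_at_epoch(epoch, config.radius_start, config.radius_end,
                                 config.radius_ramp_epochs)
        model.train()
        order = rng.permutation(n)
        epoch_loss = []
        for lo in range(0, n, config.batch_size):
            frames, targets = [], []
            for idx in order[lo:lo + config.batch_size]:
                frame, pose = train_pairs[idx]
                if pipeline is not None:
                    frame, pose = pipeline(frame, pose, rng)
                scale = (frame.width / hm, frame.height / hm)
                targets.append(encode_pose(pose, (hm, hm), scale, radius).maps)
                frames.append(frame)
            x = frames_to_input(frames, model.config.input_size)
            pred = model(x)
            loss = pose_loss(pred, np.stack(targets))
            opt.zero_grad()
            loss.backward()
            opt.step()
            if sched is not None:
                sched.step()
            epoch_loss.append(loss.item())
        val_auc = _validation_auc(model, val_pairs, config) if val_pairs else 0.0
        history.append({"epoch": epoch, "loss": float(np.mean(epoch_loss)),
                        "val_auc": val_auc, "radius": radius, "lr": opt.lr})
        if val_auc > best_auc:
            best_auc, best_state, since_best = val_auc, model.state_dict(), 0
        else:
            since_best += 1
            if val_pairs and since_best >= config.patience:
                break
    model.load_state_dict(best_state)
    model.eval()
    return best_auc, history


def _build_and_prime(config: RunConfig, priming_pairs, val_pairs, seed: int):
    from dataclasses import replace

    model = build_pose_net(replace(config.pose_net, seed=seed))
    if priming_pairs:
        rng = np.random.default_rng(derive_seed(seed, "priming"))
        train_supervised(model, priming_pairs, val_pairs, config, rng,
                         pipeline=None, epochs=config.priming_epochs,
                         one_cycle=False, lr=config.priming_lr)
    return model


def run_training(manifest, config: RunConfig, dataset_dir,
                 priming_pairs=None, run_dir=None):
    """Full two-phase semi-supervised training on a dataset manifest.

    Returns ``(model, history)`` where history records, per semi-supervised
    iteration, the flip-averaged validation AUC% of that iteration's best
    checkpoint and the fraction of pseudo-labels the filter accepted.  The
    returned model is the best checkpoint across all iterations.
    """
    from .fixtures import load_records

    annotated = [(f, p) for f, p, _ in
                 load_records(manifest, dataset_dir, split="train", cover="none")
                 if p is not None]
    if not annotated:
        raise ValueError("manifest has no annotated uncovered training frames")
    covered_train = [f for f, p, r in load_records(manifest, dataset_dir,
                                                   split="train")
                     if r.cover in ("thin", "thick")]
    val_pairs = [(f, p) for f, p, _ in
                 load_records(manifest, dataset_dir, split="val")
                 if p is not None]

    pipeline = None
    if config.p_cover > 0 and covered_train:
        bank = estimate_attenuation_factors(covered_train)
        pipeline = AugmentationPipeline(
            bank, p_cover=config.p_cover, p_noise=config.p_noise,
            p_occlude=config.p_occlude, p_flip=config.p_flip,
            noise_sigma=config.noise_sigma,
            wrinkle_roughness=config.wrinkle_roughness)

    priming_pairs = priming_pairs if priming_pairs is not None else annotated
    disc = None
    history = {"iterations": [], "config_seed": config.seed}
    best_overall, best_state = -1.0, None
    selected: list = []

    for iteration in range(config.max_iterations + 1):
        seed_it = derive_seed(config.seed, f"iteration-{iteration}")
        rng = np.random.default_rng(seed_it)
        if iteration == 0 or config.reinit_each_iteration:
            model = _build_and_prime(config, priming_pairs, val_pairs, seed_it)
        train_items = list(annotated) + [
            (frame, decode_pose(stack,
                                RefinementParams(config.refine_window,
                                                 config.refine_iterations)))
            for frame, stack, _ in selected]
        train_supervised(model, train_items, val_pairs, config, rng,
                         pipeline=pipeline, epochs=config.adapt_epochs,
                         one_cycle=True)
        val_auc = _validation_auc(model, val_pairs, config,
                                  flip_averaged=True) if val_pairs else 0.0
        entry = {"iteration": iteration, "val_auc": val_auc,
                 "selected_fraction": (len(selected) / len(covered_train)
                                       if covered_train else 0.0),
                 "n_selected": len(selected)}
        history["iterations"].append(entry)
        improved = val_auc > best_overall
        if improved:
            best_overall, best_state = val_auc, model.state_dict()
        if iteration == config.max_iterations:
            break
        if iteration > 0 and not improved:
            break  # no improvement between iterations: stop
        if not covered_train:
            break
        # pseudo-label every covered frame afresh (prior picks are re-scored)
        stacks = pseudo_label(model, covered_train)
        if config.filter_policy == "discriminator":
            if disc is None:
                # train on augmented (incl. synthetically covered) frames so
                # scores transfer to the covered domain being pseudo-labeled
                disc_rng = np.random.default_rng(
                    derive_seed(config.seed, "disc-aug"))
                disc_samples = []
                for f, p in annotated:
                    if pipeline is not None:
                        f, p = pipeline(f, p, disc_rng)
                    disc_samples.append((f, p))
                disc = build_pose_discriminator(
                    input_size=config.disc_input_size,
                    seed=derive_seed(config.seed, "discriminator"))
                disc, _ = train_pose_discriminator(
                    disc_samples, disc, epochs=config.disc_epochs,
                    lr=config.disc_lr, batch_size=config.batch_size,
                    rng_seed=derive_seed(config.seed, "disc-train"),
                    heatmap_shape=(model.config.heatmap_size,
                                   model.config.heatmap_size),
                    scale=(covered_train[0].width / model.config.heatmap_size,
                           covered_train[0].height / model.config.heatmap_size),
                    radius=config.radius_end)
            scores = [disc.score(f, s).score
                      for f, s in zip(covered_train, stacks)]
        else:
            scores = [1.0] * len(covered_train)
        batch = PseudoLabelBatch(
            items=[(f, s, sc) for f, s, sc in
                   zip(covered_train, stacks, scores)],
            iteration=iteration, tau=config.tau)
        selected = filter_pseudo_labels(batch, config.filter_policy, rng)

    history["final_auc"] = best_overall
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    if run_dir is not None:
        from pathlib import Path
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        with open(run_dir / "history.json", "w") as fh:
            json.dump(history, fh, indent=1)
        config.save_yaml(run_dir / "config.yaml")
        from .models import save_checkpoint
        save_checkpoint(model, run_dir / "model.npz",
                        {"final_auc": best_overall})
    return model, history
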