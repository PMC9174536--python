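"""Training loop, dataset splitting, checkpointing and end-to-end evaluation.

Optimization follows the standard recipe for this class of segmentation
network: Adam (first-moment coefficient 0.9, second 0.999) with additive L2
weight decay 1e-4, batch size 16, and the poly learning-rate policy

    lr(iter) = base_lr * (1 - iter / max_iter) ** power

with base_lr 4e-3 and power 0.9.  All randomness (splits, batch order,
augmentation draws) derives from the config seed, so identically seeded runs
on one device produce bit-identical loss histories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autograd import Adam, Tensor
from .loss_metrics import (
    LossParams,
    MetricsReport,
    dice_coefficient,
    evaluate_predictions,
    total_loss,
)
from .model import BottleneckResidualUNet, NetConfig, build_network
from .preprocess import AugmentParams, SamplePair, augment_pair, resize

__all__ = [
    "TrainConfig",
    "SplitSpec",
    "poly_lr",
    "split_dataset",
    "train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = "angioseg-checkpoint-1"


@dataclass(frozen=True)
class TrainConfig:
    base_lr: float = 4e-3
    power: float = 0.9
    max_iter: int = 300
    batch_size: int = 16
    weight_decay: float = 1e-4
    momentum_beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    strategy: str = "none"
    augment: AugmentParams | None = None
    loss: LossParams = field(default_factory=LossParams)
    resize_to: tuple | None = None
    val_fraction: float = 0.0
    val_every: int = 50

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if not (0.0 < self.power <= 1.0):
            raise ValueError("power must lie in (0, 1]")
        if self.batch_size < 1 or self.max_iter < 1:
            raise ValueError("batch_size and max_iter must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    train_count: int
    test_count: int
    seed: int = 0


def poly_lr(cfg: TrainConfig, iteration: int) -> float:
    """base_lr * (1 - iter/max_iter)**power; strictly decreasing in iter."""
    if not (0 <= iteration <= cfg.max_iter):
        raise ValueError(
            f"iteration {iteration} outside [0, {cfg.max_iter}]")
    return cfg.base_lr * (1.0 - iteration / cfg.max_iter) ** cfg.power


def split_dataset(pairs: list, spec: SplitSpec):
    """Seeded shuffle then partition into disjoint, exhaustive train/test."""
    if spec.train_count + spec.test_count != len(pairs):
        raise ValueError(
            f"split counts {spec.train_count}+{spec.test_count} "
            f"do not sum to dataset size {len(pairs)}")
    order = np.random.default_rng(spec.seed).permutation(len(pairs))
    train_idx = order[:spec.train_count]
    test_idx = order[spec.train_count:]
    return ([pairs[i] for i in train_idx], [pairs[i] for i in test_idx])


def _stack_batch(pairs, cfg: TrainConfig, iteration: int):
    """Assemble one (B, 1, H, W) batch, applying seeded augmentation."""
    imgs, masks = [], []
    for j, pair in enumerate(pairs):
        if cfg.augment is not None:
            pair = augment_pair(pair, seed=(cfg.seed, iteration, j),
                                params=cfg.augment)
        imgs.append(pair.image.astype(np.float32))
        masks.append(pair.mask.astype(np.float32))
    return (np.stack(imgs)[:, None], np.stack(masks)[:, None])


def train(net: BottleneckResidualUNet, pairs: list, cfg: TrainConfig,
          log_every: int = 0, progress=None):
    """Train in place; returns a history dict of per-iteration loss and LR.

    Mini-batches cycle through a seeded shuffled order, reshuffled every
    epoch; the poly schedule is advanced once per iteration.  A non-finite
    loss aborts with a diagnostic rather than training on.

    When ``cfg.val_fraction`` > 0 (and the set is large enough to spare a
    sample), a seeded held-out fraction is scored by Dice every
    ``cfg.val_every`` iterations and the best-scoring weights are kept in
    ``history["best_state"]`` alongside the final ones.
    """
    if not pairs:
        raise ValueError("empty training set")
    rng = np.random.default_rng((cfg.seed, 0xBA7C))
    val_pairs = []
    if cfg.val_fraction > 0.0:
        n_val = int(round(len(pairs) * cfg.val_fraction))
        if 0 < n_val < len(pairs):
            pairs, val_pairs = split_dataset(
                pairs, SplitSpec(len(pairs) - n_val, n_val, seed=cfg.seed))
    opt = Adam(net.parameters(), lr=cfg.base_lr, beta1=cfg.momentum_beta1,
               beta2=cfg.beta2, weight_decay=cfg.weight_decay)
    history = {"loss": [], "lr": []}
    if val_pairs:
        history["val_dice"] = []
        history["best_state"] = None
        best_dice = -1.0
    order = rng.permutation(len(pairs))
    cursor = 0
    net.train()
    for it in range(cfg.max_iter):
        idx = []
        for _ in range(min(cfg.batch_size, len(pairs))):
            if cursor >= len(order):
                order = rng.permutation(len(pairs))
                cursor = 0
            idx.append(int(order[cursor]))
            cursor += 1
        xb, yb = _stack_batch([pairs[i] for i in idx], cfg, it)
        lr = poly_lr(cfg, it)
        opt.lr = lr
        opt.zero_grad()
        out = net(Tensor(xb))
        loss = total_loss(yb, out, cfg.loss)
        value = loss.item()
        if not np.isfinite(value):
            raise FloatingPointError(
                f"non-finite training loss {value} at iteration {it}")
        loss.backward()
        opt.step()
        history["loss"].append(value)
        history["lr"].append(lr)
        if val_pairs and (it % cfg.val_every == cfg.val_every - 1
                          or it == cfg.max_iter - 1):
            vd = training_set_dice(net, val_pairs)
            history["val_dice"].append((it, vd))
            if vd > best_dice:
                best_dice = vd
                history["best_state"] = net.state_dict()
            net.train()
        if log_every and (it % log_every == 0 or it == cfg.max_iter - 1):
            msg = f"iter {it:5d}  lr {lr:.6f}  loss {value:.5f}"
            (progress or print)(msg)
    return net, history


def predict_pairs(net: BottleneckResidualUNet, pairs: list,
                  resize_to: tuple | None = None):
    """Forward passes in eval mode; returns (masks, probability maps)."""
    masks, probs = [], []
    for pair in pairs:
        img, msk = pair.image, pair.mask
        if resize_to is not None:
            img = resize(img, resize_to, mode="bilinear")
            msk = resize(msk, resize_to, mode="nearest")
        probs.append(net.predict(img))
        masks.append(msk)
    return masks, probs


def evaluate(net: BottleneckResidualUNet, pairs: list,
             cfg: TrainConfig | None = None,
             threshold: float = 0.5) -> MetricsReport:
    """Metrics over pooled test pixels, after any configured test-time resize."""
    if not pairs:
        raise ValueError("empty test set")
    resize_to = cfg.resize_to if cfg is not None else None
    masks, probs = predict_pairs(net, pairs, resize_to)
    return evaluate_predictions(masks, probs, threshold)


def training_set_dice(net: BottleneckResidualUNet, pairs: list,
                      threshold: float = 0.5) -> float:
    masks, probs = predict_pairs(net, pairs)
    return dice_coefficient(np.stack(masks), np.stack(probs), threshold)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(net: BottleneckResidualUNet, path) -> None:
    """Serialized weights (.npz) with a JSON sidecar carrying the config."""
    path = Path(path)
    state = net.state_dict()
    np.savez(path.with_suffix(".npz"), **state)
    from . import __version__

    cfg = asdict(net.cfg)
    cfg["se"] = asdict(net.cfg.se)
    sidecar = {"version": CHECKPOINT_VERSION, "code_version": __version__,
               "net_config": cfg}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> BottleneckResidualUNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unrecognized checkpoint version in {path}")
    raw = dict(sidecar["net_config"])
    from .model import SeConfig  # local import to avoid cycle at module load

    raw["se"] = SeConfig(**raw["se"])
    for key in ("stage_widths", "up_widths"):
        raw[key] = tuple(raw[key])
    net = build_network(NetConfig(**raw))
    with np.load(path.with_suffix(".npz")) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net
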