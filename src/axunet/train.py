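"""Training, evaluation and prediction loops.

The recipe: SGD (initial learning rate 0.01, momentum 0.9, weight decay
1e-4) under a cosine-annealing warm-restart schedule, batch size 4, with
the composite edge-aware loss; each epoch ends with a validation pass and
the checkpoint with the best validation mDice is kept.  Datasets are split
into train/validation/test at 8:1:1 by default.

All randomness (parameter init, shuffling, augmentation) is derived from a
single integer seed, so a run's loss trace is exactly reproducible.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .losses import LossConfig, LossWeights, bce_loss, dice_loss, total_loss
from .metrics import aggregate, confusion, scores, write_report
from .network import NetworkConfig, SegNet
from .synthdata import SegSample, augment

__all__ = ["TrainConfig", "RunRecord", "split_dataset", "train", "evaluate",
           "predict"]


@dataclass
class TrainConfig:
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    restart_period: float = 10.0    # warm-restart cycle length, epochs
    restart_mult: float = 2.0
    batch_size: int = 4
    max_epochs: int = 150
    seed: int = 0
    augment: bool = True
    val_fraction: float = 0.1
    test_fraction: float = 0.1
    loss_weights: LossWeights = field(default_factory=LossWeights)
    loss: LossConfig = field(default_factory=LossConfig)
    log_every: int = 0              # steps between console lines; 0 = silent

    def __post_init__(self):
        if min(self.lr, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("lr, batch_size and max_epochs must be positive")


@dataclass
class RunRecord:
    epochs: list            # per-epoch dicts: losses, val metrics, lr
    best_epoch: int
    best_val_dice: float
    split: dict             # index lists for train/val/test
    seed: int
    train_config: dict
    network_config: dict

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def split_dataset(n: int, cfg: TrainConfig,
                  rng: np.random.Generator) -> dict[str, list[int]]:
    """Shuffled train/val/test split (8:1:1 by default)."""
    idx = rng.permutation(n).tolist()
    n_val = int(round(cfg.val_fraction * n))
    n_test = int(round(cfg.test_fraction * n))
    n_train = n - n_val - n_test
    return {
        "train": idx[:n_train],
        "val": idx[n_train : n_train + n_val],
        "test": idx[n_train + n_val :],
    }


def _batch_arrays(samples: Sequence[SegSample]):
    images = np.stack([s.image for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples]).astype(np.float32)[:, None]
    edges = np.stack([s.edge for s in samples]).astype(np.float32)[:, None]
    return images, masks, edges


def _validate(net: SegNet, samples: Sequence[SegSample], threshold: float = 0.5):
    """Per-image metrics plus mean edge BCE, in evaluation mode."""
    net.eval()
    per_image, edge_bces = [], []
    with ad.no_grad():
        for s in samples:
            out = net(Tensor(s.image[None]))
            prob = 1.0 / (1.0 + np.exp(-out.seg_logits.data[0, 0]))
            per_image.append(scores(confusion(prob, s.mask, threshold)))
            if out.edge_logits is not None:
                eprob = 1.0 / (1.0 + np.exp(-out.edge_logits.data[0, 0]))
                edge_bces.append(
                    bce_loss(eprob, s.edge.astype(np.float32)).item()
                )
    net.train()
    agg = aggregate(per_image)
    agg["edge_bce"] = float(np.mean(edge_bces)) if edge_bces else float("nan")
    return per_image, agg


def train(net_cfg: NetworkConfig, train_cfg: TrainConfig,
          samples: Sequence[SegSample], out_dir) -> RunRecord:
    """Run the full training loop; returns the record and writes
    ``best.npz`` + ``record.json`` into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    nn.seed_all(train_cfg.seed)
    rng = np.random.default_rng([train_cfg.seed, 1])

    net = SegNet(net_cfg)
    opt = nn.SGD(net.parameters(), lr=train_cfg.lr, momentum=train_cfg.momentum,
                 weight_decay=train_cfg.weight_decay)
    sched = nn.CosineAnnealingWarmRestarts(opt, train_cfg.restart_period,
                                           train_cfg.restart_mult)

    split = split_dataset(len(samples), train_cfg, rng)
    train_set = [samples[i] for i in split["train"]]
    val_set = [samples[i] for i in split["val"]] or train_set

    best_dice, best_epoch = -1.0, -1
    epochs_log = []
    ckpt_path = os.path.join(out_dir, "best.npz")
    steps_per_epoch = max(1, int(np.ceil(len(train_set) / train_cfg.batch_size)))

    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(len(train_set))
        epoch_parts = []
        for step in range(steps_per_epoch):
            lr = sched.step(epoch + step / steps_per_epoch)
            batch_idx = order[step * train_cfg.batch_size :
                              (step + 1) * train_cfg.batch_size]
            if batch_idx.size == 0:
                continue
            batch = [train_set[i] for i in batch_idx]
            if train_cfg.augment:
                batch = [augment(s, rng) for s in batch]
            images, masks, edges = _batch_arrays(batch)

            out = net(Tensor(images))
            seg_p = ad.sigmoid(out.seg_logits)
            if out.edge_logits is not None:
                edge_p = ad.sigmoid(out.edge_logits)
                loss, parts = total_loss(seg_p, masks, edge_p, edges,
                                         train_cfg.loss_weights, train_cfg.loss)
            else:
                w, lc = train_cfg.loss_weights, train_cfg.loss
                bce = bce_loss(seg_p, masks, reduction=lc.reduction)
                dice = dice_loss(seg_p, masks, eps=lc.dice_epsilon,
                                 as_printed=lc.dice_as_printed)
                loss = w.alpha * bce + w.beta * dice
                parts = {"bce": bce.item(), "dice": dice.item(),
                         "ohem": 0.0, "total": loss.item()}
            if not np.isfinite(parts["total"]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step}: {parts}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_parts.append(parts)
            if train_cfg.log_every and (step % train_cfg.log_every == 0):
                print(f"epoch {epoch} step {step} lr {lr:.5f} "
                      f"loss {parts['total']:.4f}")

        _, val_agg = _validate(net, val_set)
        mean_parts = {k: float(np.mean([p[k] for p in epoch_parts]))
                      for k in epoch_parts[0]}
        epochs_log.append({"epoch": epoch, "lr": lr, "train_loss": mean_parts,
                           "val": val_agg})
        if val_agg["dice"] > best_dice:
            best_dice, best_epoch = val_agg["dice"], epoch
            net.save(ckpt_path)

    record = RunRecord(
        epochs=epochs_log, best_epoch=best_epoch, best_val_dice=best_dice,
        split=split, seed=train_cfg.seed, train_config=asdict(train_cfg),
        network_config=asdict(net_cfg),
    )
    record.save(os.path.join(out_dir, "record.json"))
    return record


def evaluate(checkpoint, samples: Sequence[SegSample],
             report_path=None, threshold: float = 0.5) -> dict[str, float]:
    """Per-image and aggregate metrics of a checkpoint on ``samples``."""
    net = checkpoint if isinstance(checkpoint, SegNet) else SegNet.load(checkpoint)
    per_image, agg = _validate(net, samples, threshold)
    if report_path is not None:
        write_report(report_path, per_image)
    return agg


def predict(checkpoint, images_dir, out_dir, threshold: float = 0.5,
            save_prob: bool = False) -> list[str]:
    """Segment every readable image in ``images_dir``; write 0/255 masks."""
    net = checkpoint if isinstance(checkpoint, SegNet) else SegNet.load(checkpoint)
    net.eval()
    size = net.cfg.input_size
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name in sorted(os.listdir(images_dir)):
        path = os.path.join(images_dir, name)
        try:
            img = Image.open(path).convert("RGB")
        except Exception:
            print(f"warning: skipping unreadable image {path}")
            continue
        orig = img.size
        arr = np.asarray(img.resize((size, size), Image.BILINEAR),
                         dtype=np.float32) / 255.0
        with ad.no_grad():
            out = net(Tensor(arr.transpose(2, 0, 1)[None]))
        prob = 1.0 / (1.0 + np.exp(-out.seg_logits.data[0, 0]))
        mask = Image.fromarray(((prob >= threshold) * 255).astype(np.uint8))
        if orig != (size, size):
            mask = mask.resize(orig, Image.NEAREST)
        stem = os.path.splitext(name)[0]
        out_path = os.path.join(out_dir, f"{stem}_mask.png")
        mask.save(out_path)
        written.append(out_path)
        if save_prob:
            pimg = Image.fromarray(np.round(prob * 255).astype(np.uint8))
            if orig != (size, size):
                pimg = pimg.resize(orig, Image.BILINEAR)
            pimg.save(os.path.join(out_dir, f"{stem}_prob.png"))
    return written
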