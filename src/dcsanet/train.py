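"""Training and evaluation: Adam on per-pixel cross-entropy, dataset-level
MIoU, and the ablation harness.

The published recipe is followed: Adam with initial learning rate 0.001,
batch size 4, 400 epochs by default.  ``TrainConfig.target_miou`` allows
stopping early once the train-set MIoU reaches a threshold, which the small
CPU experiments use.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .autograd import Var, softmax_cross_entropy
from .metrics import ConfusionCounts, MetricsReport, confusion_from_masks, miou
from .model import DCSANet, ModelConfig, build_model, model_summary

__all__ = [
    "TrainConfig",
    "Adam",
    "train",
    "evaluate",
    "run_ablation",
    "samples_to_batch",
    "write_history_csv",
]


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    initial_lr: float = 0.001
    batch_size: int = 4
    epochs: int = 400
    seed: int = 0
    eval_every: int = 5
    target_miou: float | None = None

    def __post_init__(self):
        if self.initial_lr <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning rate, batch size and epochs must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


class Adam:
    def __init__(self, params, lr=0.001, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def samples_to_batch(samples):
    """Stack SegmentationSamples into (images NCHW float32 in [0,1], labels)."""
    images = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    images = images.transpose(0, 3, 1, 2)
    labels = np.stack([s.mask for s in samples]).astype(np.int64)
    return images, labels


def _train_miou(model, samples, num_classes, batch_size):
    conf = ConfusionCounts.zeros(num_classes)
    for i in range(0, len(samples), batch_size):
        images, labels = samples_to_batch(samples[i : i + batch_size])
        pred = model.predict(images)
        conf = conf + confusion_from_masks(pred, labels, num_classes)
    return miou(conf).miou


def train(model: DCSANet, split, cfg: TrainConfig, checkpoint_path=None, verbose=False):
    """Minimise cross-entropy on ``split.train``; track validation loss/MIoU.

    ``split`` may be a DatasetSplit or any object with ``train``/``val``
    sample lists (``val`` may be empty).  Returns the history: one dict per
    epoch with train_loss and, on evaluation epochs, train/val MIoU.
    """
    train_samples = list(split.train)
    val_samples = list(getattr(split, "val", []) or [])
    if not train_samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    k = model.cfg.num_classes
    opt = Adam(model.parameters(), lr=cfg.initial_lr)
    history = []
    best_val = -np.inf
    for epoch in range(1, cfg.epochs + 1):
        model.train()
        order = rng.permutation(len(train_samples))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            batch = [train_samples[j] for j in order[i : i + cfg.batch_size]]
            images, labels = samples_to_batch(batch)
            opt.zero_grad()
            loss = softmax_cross_entropy(model.forward(images), labels)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {float(loss.data)}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if epoch % cfg.eval_every == 0 or epoch == cfg.epochs:
            record["train_miou"] = _train_miou(model, train_samples, k, cfg.batch_size)
            if val_samples:
                val_report = evaluate(model, val_samples, batch_size=cfg.batch_size)
                val_images, val_labels = samples_to_batch(val_samples)
                model.eval()
                val_loss = softmax_cross_entropy(model.forward(val_images), val_labels)
                record["val_loss"] = float(val_loss.data)
                record["val_miou"] = val_report.miou
                if checkpoint_path is not None and val_report.miou > best_val:
                    best_val = val_report.miou
                    from .model import save_checkpoint

                    save_checkpoint(model, checkpoint_path)
        history.append(record)
        if verbose:
            print(", ".join(f"{k_}={v:.4g}" if isinstance(v, float) else f"{k_}={v}"
                            for k_, v in record.items()))
        if cfg.target_miou is not None and record.get("train_miou", 0) >= cfg.target_miou:
            break
    if checkpoint_path is not None and not val_samples:
        from .model import save_checkpoint

        save_checkpoint(model, checkpoint_path)
    return history


def evaluate(model: DCSANet, samples, batch_size=4) -> MetricsReport:
    """Dataset-level MIoU: confusion accumulated over all samples first."""
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample list")
    k = model.cfg.num_classes
    conf = ConfusionCounts.zeros(k)
    for i in range(0, len(samples), batch_size):
        images, labels = samples_to_batch(samples[i : i + batch_size])
        pred = model.predict(images)
        conf = conf + confusion_from_masks(pred, labels, k)
    return miou(conf)


def run_ablation(configs, split, train_cfg: TrainConfig, input_size=512, csv_path=None,
                 seeds=None, verbose=False):
    """Train/evaluate one model per config; emit rows of FLOPs(G), Param(M), MIoU(%).

    ``configs`` maps row names to ModelConfig.  ``seeds`` (optional list)
    repeats each row and reports mean +/- sd of MIoU.
    """
    rows = []
    seeds = list(seeds) if seeds is not None else [train_cfg.seed]
    eval_samples = list(getattr(split, "test", []) or []) or list(split.train)
    for name, cfg in configs.items():
        summary = model_summary(build_model(cfg), input_size=input_size)
        mious = []
        for seed in seeds:
            run_cfg = TrainConfig(
                initial_lr=train_cfg.initial_lr, batch_size=train_cfg.batch_size,
                epochs=train_cfg.epochs, seed=seed, eval_every=train_cfg.eval_every,
                target_miou=train_cfg.target_miou,
            )
            model = build_model(cfg, seed=seed)
            train(model, split, run_cfg, verbose=verbose)
            mious.append(evaluate(model, eval_samples).miou)
        row = {
            "model": name,
            "flops_g": round(summary.flops_billions, 3),
            "param_m": round(summary.params_millions, 4),
            "miou_pct": round(100 * float(np.mean(mious)), 2),
        }
        if len(seeds) > 1:
            row["miou_sd"] = round(100 * float(np.std(mious)), 2)
        rows.append(row)
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    return rows


def write_history_csv(history, path):
    fields = ["epoch", "train_loss", "train_miou", "val_loss", "val_miou"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, extrasaction="ignore")
        writer.writeheader()
        writer.writerows(history)
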