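"""Training protocol: mini-batch SGD (momentum 0.9, weight decay 5e-4 on
conv/linear weights), cosine-annealed learning rate from 0.01 down to 1e-9,
cross-entropy loss over softmax, per-epoch test evaluation and
best-checkpoint retention."""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .backbone import RemShuffleNet
from .metrics import MetricsReport, evaluate_predictions
from .nn import functional as F
from .nn.tensor import Tensor


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    epochs: int = 60
    lr0: float = 0.01
    lr_min: float = 1e-9
    momentum: float = 0.9
    weight_decay: float = 0.0005
    seed: int = 0

    def __post_init__(self):
        if self.lr_min >= self.lr0:
            raise ValueError("lr_min must be below lr0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


@dataclass
class TrainHistory:
    epoch: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_accuracy: float = -1.0
    best_state: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epoch, "lr": self.lr,
                             "train_loss": self.train_loss,
                             "test_accuracy": self.test_accuracy})


def cosine_lr(t: int, total: int, lr0: float = 0.01, lr_min: float = 1e-9) -> float:
    """Cosine annealing: lr(t) = lr_min + (lr0-lr_min)(1+cos(pi t/T))/2.

    Hits lr0 exactly at t=0 and lr_min exactly at t=T; strictly decreasing
    in between.
    """
    if t < 0 or t > total:
        raise ValueError(f"epoch index {t} outside [0, {total}]")
    return lr_min + (lr0 - lr_min) * (1 + math.cos(math.pi * t / total)) / 2


def evaluate(model: RemShuffleNet, x: np.ndarray, y: np.ndarray, *,
             grouping: dict[int, str] | None = None,
             batch_size: int = 64) -> MetricsReport:
    """Argmax predictions over the softmax, scored with the full metric suite."""
    if len(x) == 0:
        raise ValueError("empty test set")
    preds = model.predict(x, batch_size=batch_size)
    return evaluate_predictions(y, preds, model.cfg.num_classes,
                                grouping=grouping)


def train(model: RemShuffleNet, train_set: tuple[np.ndarray, np.ndarray],
          test_set: tuple[np.ndarray, np.ndarray], cfg: TrainConfig,
          verbose: bool = False) -> TrainHistory:
    """Run the full training protocol; reproducible under cfg.seed.

    The learning rate recorded at epoch e equals cosine_lr(e, cfg.epochs).
    The weights of the best-test-accuracy epoch are kept in
    ``history.best_state``.
    """
    xtr, ytr = train_set
    xte, yte = test_set
    if len(xtr) == 0 or len(xte) == 0:
        raise ValueError("empty dataset")
    k = model.cfg.num_classes
    if ytr.max() >= k or yte.max() >= k or min(ytr.min(), yte.min()) < 0:
        raise ValueError("label out of range for the model's class count")

    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    history = TrainHistory()
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.lr0, cfg.lr_min)
        opt.lr = lr
        model.train()
        order = rng.permutation(len(xtr))
        losses = []
        for start in range(0, len(xtr), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model(Tensor(xtr[idx]))
            loss = F.cross_entropy(logits, ytr[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        acc = float(np.mean(model.predict(xte) == yte))
        history.epoch.append(epoch)
        history.lr.append(lr)
        history.train_loss.append(float(np.mean(losses)))
        history.test_accuracy.append(acc)
        if acc > history.best_accuracy:
            history.best_accuracy = acc
            history.best_epoch = epoch
            history.best_state = copy.deepcopy(model.state_dict())
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.6f}  "
                  f"loss {history.train_loss[-1]:.4f}  test acc {acc:.4f}")
    return history


def save_run(run_dir, model: RemShuffleNet, history: TrainHistory,
             cfg: TrainConfig) -> None:
    """Persist a run: history CSV, best checkpoint (npz), resolved configs."""
    run = Path(run_dir)
    run.mkdir(parents=True, exist_ok=True)
    history.to_frame().to_csv(run / "history.csv", index=False)
    if history.best_state is not None:
        np.savez(run / "best_checkpoint.npz", **history.best_state)
    (run / "train_config.json").write_text(json.dumps(asdict(cfg), indent=2))
    (run / "model_config.json").write_text(model.cfg.to_json())
    from .backbone import parameter_manifest
    (run / "parameter_manifest.json").write_text(
        json.dumps(parameter_manifest(model), indent=2))


def load_checkpoint(model: RemShuffleNet, path) -> None:
    with np.load(path) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
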