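"""Training recipe: Adam + weight decay, inverse-frequency weighted sampling,
reduce-on-plateau scheduling, early stopping on validation loss, and the
3-seed hold-out protocol with a fixed test set."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._errors import InvalidConfigError
from . import nn
from .config import ModelConfig
from .datapipe import (
    ClipDataset,
    ExamManifest,
    build_clip_index,
    make_splits,
    sampler_weights,
)
from .evaluation import TRAIN_MASK_VALUE, mask_logits_batch
from .models import build_model

__all__ = ["TrainConfig", "TrainResult", "train", "run_holdout", "HoldoutResult"]


@dataclass
class TrainConfig:
    """Hyperparameters.  Defaults follow the published recipe: lr 1e-5 (2D)
    or 1e-4 (3D/(2+1)D), weight decay 1e-4, batch 128 (2D) or 8 (clips),
    up to 200 epochs with patience-10 early stopping on validation loss and
    a reduce-on-plateau scheduler."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 200
    early_stop_patience: int = 10
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    seed: int = 0
    augment: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise InvalidConfigError("rates must be non-negative")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise InvalidConfigError("batch_size and max_epochs must be >= 1")
        if not 0 <= self.early_stop_patience < self.max_epochs:
            raise InvalidConfigError("patience must be < max_epochs")

    @classmethod
    def defaults_for(cls, variant: str, **overrides) -> "TrainConfig":
        base = dict(learning_rate=1e-5, batch_size=128) if variant == "2d" else dict(
            learning_rate=1e-4, batch_size=8
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class TrainResult:
    history: pd.DataFrame
    best_state: list[np.ndarray]
    best_epoch: int
    best_val_loss: float

    def save_history(self, path) -> None:
        self.history.to_csv(path, index=False)


def _allowed_matrix(scan_ids: np.ndarray, priors: dict[int, list[int]], k: int) -> np.ndarray:
    allowed = np.zeros((len(scan_ids), k), dtype=bool)
    for i, sid in enumerate(scan_ids):
        allowed[i, list(priors[int(sid)])] = True
    return allowed


def _epoch_pass(model, dataset, indices, batch_size, priors, train, optimizer, rng):
    """One pass over ``indices``; returns (mean loss, accuracy)."""
    losses, correct, total = [], 0, 0
    scan_ids = dataset.scan_ids
    for lo in range(0, len(indices), batch_size):
        batch_idx = indices[lo : lo + batch_size]
        x, y = dataset.batch(batch_idx, rng=rng if train else None)
        logits = model.logits(x, train=train)
        if priors is not None:
            allowed = _allowed_matrix(scan_ids[batch_idx], priors, model.num_classes)
            logits = mask_logits_batch(logits, allowed, fill=TRAIN_MASK_VALUE)
        loss, dlogits = nn.cross_entropy(logits, y)
        if train:
            model.zero_grad()
            model.backward(dlogits)
            optimizer.step()
        losses.append(loss * len(batch_idx))
        correct += int((logits.argmax(axis=1) == y).sum())
        total += len(batch_idx)
    return float(np.sum(losses) / total), correct / total


def train(
    model: nn.Network,
    train_set: ClipDataset,
    val_set: ClipDataset,
    config: TrainConfig,
    priors: dict[int, list[int]] | None = None,
) -> TrainResult:
    """Optimise softmax cross-entropy with class-balanced sampling.

    Per epoch, len(train_set) samples are drawn with replacement with
    probability proportional to the inverse frequency of each sample's
    class.  If ``priors`` is given, logits of classes disallowed in the
    sample's scan are suppressed (large negative additive mask) before the
    loss.  Stops early when validation loss has not improved for
    ``early_stop_patience`` epochs and restores the best checkpoint.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise InvalidConfigError("datasets must be non-empty")
    labels = train_set.labels
    present = set(labels.tolist())
    if len(present) < model.num_classes:
        warnings.warn(
            f"only {len(present)} of {model.num_classes} classes present in the "
            "training set; sampler weights are computed over present classes",
            stacklevel=2,
        )
    weights = sampler_weights(labels)
    probs = weights / weights.sum()
    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(
        model.parameters(), lr=config.learning_rate, weight_decay=config.weight_decay
    )

    rows = []
    best_val = np.inf
    best_state = model.get_state()
    best_epoch = 0
    stall = 0
    sched_stall = 0
    val_indices = np.arange(len(val_set))
    for epoch in range(1, config.max_epochs + 1):
        order = rng.choice(len(train_set), size=len(train_set), replace=True, p=probs)
        train_loss, train_acc = _epoch_pass(
            model, train_set, order, config.batch_size, priors, True, optimizer,
            rng if config.augment else None,
        )
        val_loss, val_acc = _epoch_pass(
            model, val_set, val_indices, config.batch_size, priors, False, None, None
        )
        rows.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "train_acc": train_acc,
                "val_loss": val_loss,
                "val_acc": val_acc,
                "lr": optimizer.lr,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
            best_epoch = epoch
            stall = 0
            sched_stall = 0
        else:
            stall += 1
            sched_stall += 1
            if sched_stall > config.scheduler_patience:
                optimizer.lr *= config.scheduler_factor
                sched_stall = 0
            if stall >= config.early_stop_patience:
                break
    model.set_state(best_state)
    return TrainResult(
        history=pd.DataFrame(rows),
        best_state=best_state,
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
    )


@dataclass
class HoldoutResult:
    accuracies: list[float]
    seeds: list[int]

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std(self) -> float:
        if all(a == self.accuracies[0] for a in self.accuracies):
            return 0.0  # avoid float noise from the mean when identical
        return float(np.std(self.accuracies))


def run_holdout(
    model_config: ModelConfig,
    manifest: ExamManifest,
    clip_len: int,
    train_config: TrainConfig,
    seeds: tuple[int, ...] = (0, 1, 2),
    test_seed: int = 0,
    test_fraction: float = 0.15,
    val_fraction: float = 0.2,
    priors: dict[int, list[int]] | None = None,
    frames: dict[str, np.ndarray] | None = None,
) -> HoldoutResult:
    """Hold-out cross-validation: the test set is fixed (``test_seed``) while
    train/validation are re-randomised per seed; reports per-split test
    accuracies (mean/std on the result)."""
    if len(seeds) < 2:
        raise InvalidConfigError("need at least 2 hold-out splits")
    records = build_clip_index(manifest, clip_len)
    mode = "2d" if model_config.variant == "2d" else "3d"
    accuracies = []
    for seed in seeds:
        split = make_splits(
            manifest, test_fraction, val_fraction, seed=seed, test_seed=test_seed
        )
        train_set = ClipDataset(manifest, records, mode, patients=set(split.train), frames=frames)
        val_set = ClipDataset(manifest, records, mode, patients=set(split.val), frames=frames)
        test_set = ClipDataset(manifest, records, mode, patients=set(split.test), frames=frames)
        model, _ = build_model(model_config, seed=seed)
        cfg = TrainConfig(**{**train_config.__dict__, "seed": seed})
        train(model, train_set, val_set, cfg, priors=priors)
        _, test_acc = _epoch_pass(
            model, test_set, np.arange(len(test_set)), cfg.batch_size, priors,
            False, None, None,
        )
        accuracies.append(test_acc)
    return HoldoutResult(accuracies=accuracies, seeds=list(seeds))
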