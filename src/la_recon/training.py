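"""Dice-loss training with early stopping and best-on-validation checkpointing.

The loss is the smoothed dice overlap converted to a minimizable form::

    coefficient(p, g) = (2 * sum(p * g) + 1) / (sum(p^2) + sum(g^2) + 1)
    loss = 1 - coefficient

with the sums running over all voxels of the volume and the smoothing
constant fixed at 1.  The optimizer is ADAM (lr 1e-4, betas 0.9/0.999 by
default), batch size 1, training order reshuffled each epoch.  After every
epoch the mean dice of the thresholded (argmax) prediction on the validation
set is recorded; training stops after ``patience`` epochs without improvement
and the weights from the best validation epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .nn.model import ResidualUNet3D
from .nn.optim import Adam
from .types import LAGeometry, PartialShell

__all__ = [
    "TrainConfig",
    "DatasetSplit",
    "dice_coefficient",
    "dice_loss",
    "dice_loss_grad",
    "train",
    "TrainResult",
    "cache_dataset",
    "load_cache",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    max_epochs: int = 1000
    patience: int = 50
    batch_size: int = 1
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.adam_beta1 < self.adam_beta2 < 1:
            raise ValueError("need 0 < beta1 < beta2 < 1")
        if self.patience > self.max_epochs:
            raise ValueError(f"patience {self.patience} exceeds max_epochs {self.max_epochs}")
        if self.batch_size != 1:
            raise ValueError("only batch_size 1 is supported (3D volumes)")


Pair = tuple[PartialShell, LAGeometry]


@dataclass
class DatasetSplit:
    """Train/validation/test partitions of (shell, label) pairs.

    A given LA geometry should appear in at most one split so labels never
    repeat across partitions.
    """

    train: list[Pair]
    validation: list[Pair]
    test: list[Pair] = field(default_factory=list)


def _as_arrays(pair: Pair) -> tuple[np.ndarray, np.ndarray]:
    shell, label = pair
    x = shell.volume.astype(np.float32)[None]
    g = label.mask.astype(np.float32)
    if x.shape[1:] != g.shape:
        raise ValueError(f"shell shape {x.shape[1:]} != label shape {g.shape}")
    return x, g


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """Smoothed dice overlap; 1.0 for identical non-empty binary masks."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    num = 2.0 * float((pred * truth).sum()) + 1.0
    den = float((pred**2).sum()) + float((truth**2).sum()) + 1.0
    return num / den


def dice_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """1 - smoothed dice coefficient; in [0, 1) for valid inputs."""
    return 1.0 - dice_coefficient(pred, truth)


def dice_loss_grad(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """d(dice_loss)/d(pred), same shape as pred."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    num = 2.0 * (pred * truth).sum() + 1.0
    den = (pred**2).sum() + (truth**2).sum() + 1.0
    return (-(2.0 * truth * den - num * 2.0 * pred) / den**2).astype(np.float32)


@dataclass
class TrainResult:
    network: ResidualUNet3D
    history: pd.DataFrame
    best_epoch: int
    best_val_dice: float


def _validation_dice(network: ResidualUNet3D, pairs: list[Pair]) -> float:
    scores = []
    for pair in pairs:
        x, g = _as_arrays(pair)
        p = network.forward(x, training=False)
        scores.append(dice_coefficient(p[1] > p[0], g))
    return float(np.mean(scores))


def train(split: DatasetSplit, network: ResidualUNet3D, config: TrainConfig) -> TrainResult:
    """ADAM minimization of the dice loss with early stopping.

    Returns the network carrying the weights of the best validation epoch
    (not the final epoch) plus the per-epoch history.
    """
    if not split.train or not split.validation:
        raise ValueError("train and validation splits must be non-empty")

    optimizer = Adam(
        network.parameters(),
        learning_rate=config.learning_rate,
        beta1=config.adam_beta1,
        beta2=config.adam_beta2,
    )
    rng = np.random.default_rng([int(config.seed) % (2**31), 77])

    rows = []
    best_state = network.state_dict()
    best_dice = -np.inf
    best_epoch = -1
    epochs_without_improvement = 0

    for epoch in range(config.max_epochs):
        order = np.arange(len(split.train))
        if config.shuffle:
            rng.shuffle(order)
        losses = []
        for step, idx in enumerate(order):
            x, g = _as_arrays(split.train[idx])
            network.zero_grad()
            p = network.forward(x, training=True)
            loss = dice_loss(p[1], g)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, step {step}")
            dp = np.zeros_like(p)
            dp[1] = dice_loss_grad(p[1], g)
            network.backward(dp)
            optimizer.step()
            losses.append(loss)

        val_dice = _validation_dice(network, split.validation)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_dice": val_dice})

        if val_dice > best_dice:
            best_dice = val_dice
            best_epoch = epoch
            best_state = network.state_dict()
            epochs_without_improvement = 0
        else:
            epochs_without_improvement += 1
            if epochs_without_improvement > config.patience:
                break

    network.load_state_dict(best_state)
    history = pd.DataFrame(rows)
    return TrainResult(network=network, history=history, best_epoch=best_epoch, best_val_dice=best_dice)


def cache_dataset(pairs: list[Pair], path: str | Path) -> None:
    """Write homogeneous (shell, label) pairs to an HDF5 container.

    Datasets: ``shells`` and ``labels``, both (N, D, H, W) uint8; the voxel
    spacing is stored as a file attribute.  Reload is bit-exact.
    """
    if not pairs:
        raise ValueError("no pairs to cache")
    shapes = [p[0].volume.shape for p in pairs]
    ref = shapes[0]
    bad = [i for i, s in enumerate(shapes) if s != ref]
    bad += [i for i, p in enumerate(pairs) if p[1].mask.shape != p[0].volume.shape]
    if bad:
        raise ValueError(f"heterogeneous volume shapes in cases {sorted(set(bad))}")
    shells = np.stack([p[0].volume for p in pairs]).astype(np.uint8)
    labels = np.stack([p[1].mask for p in pairs]).astype(np.uint8)
    with h5py.File(str(path), "w") as f:
        f.create_dataset("shells", data=shells, compression="gzip")
        f.create_dataset("labels", data=labels, compression="gzip")
        f.attrs["spacing_mm"] = float(pairs[0][0].spacing_mm)


def load_cache(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a cache back; raises a descriptive error for corrupt files."""
    try:
        with h5py.File(str(path), "r") as f:
            if "shells" not in f or "labels" not in f:
                raise ValueError(f"{path} is not a dataset cache (missing datasets)")
            return f["shells"][...], f["labels"][...], float(f.attrs["spacing_mm"])
    except OSError as exc:
        raise ValueError(f"cannot read dataset cache {path}: {exc}") from exc
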