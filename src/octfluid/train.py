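"""Training loop: Smooth-Dice loss, cube-level splits, plateau LR schedule.

The loss is the Smooth Dice loss in the form

    L(X, Y) = 1 - 2 * (sum(X*Y) + 1) / (sum(X) + sum(Y) + 1),

with the soft intersection ``sum(pred * target)``.  Note the ``+1`` sits
inside the doubled numerator, so the loss reaches -1 on an empty-vs-empty
pair rather than 0; this literal form is the default, and
``conventional=True`` computes the more common ``1 - (2I+1)/(|X|+|Y|+1)``.

Optimization follows the reference schedule: SGD with Nesterov momentum
(coefficient 0.9) from an initial learning rate of 1e-3, the learning rate
multiplied by 0.3 whenever validation loss has not improved for 40 epochs,
early stopping after 80 epochs without improvement, and the returned model
is the best-validation snapshot, not the last.  "Improved" means strictly
lower than the best seen so far.  Validation slices are never augmented.

Splits are at cube level: no slice of any cube ever crosses the
train/validation/test boundary.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .augment import AugmentConfig, augment_pair
from .model import UNet, prepare_batch, resize2d
from .nn import SGD

logger = logging.getLogger(__name__)


def smooth_dice_loss(pred: np.ndarray, target: np.ndarray,
                     conventional: bool = False) -> float:
    """Smooth Dice loss between a probability grid and a binary grid.

    Default is the literal printed form ``1 - 2(I+1)/(S_p + S_t + 1)`` (range
    [-1, 1), equal to -1 when both grids are empty); ``conventional=True``
    gives ``1 - (2I+1)/(S_p + S_t + 1)``.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    inter = float((pred * target).sum())
    denom = float(pred.sum() + target.sum()) + 1.0
    if conventional:
        return 1.0 - (2.0 * inter + 1.0) / denom
    return 1.0 - 2.0 * (inter + 1.0) / denom


def _smooth_dice_loss_grad(pred: np.ndarray, target: np.ndarray
                           ) -> tuple[float, np.ndarray]:
    """Per-sample mean Smooth Dice loss over a (N, H, W) batch and d(loss)/d(pred)."""
    n = pred.shape[0]
    p = pred.reshape(n, -1).astype(np.float64)
    t = target.reshape(n, -1).astype(np.float64)
    inter = (p * t).sum(axis=1)
    denom = p.sum(axis=1) + t.sum(axis=1) + 1.0
    losses = 1.0 - 2.0 * (inter + 1.0) / denom
    # dL/dp = -2 t / D + 2 (I+1) / D^2, averaged over the batch
    grad = (-2.0 * t / denom[:, None] + 2.0 * (inter + 1.0)[:, None] / denom[:, None] ** 2) / n
    return float(losses.mean()), grad.reshape(pred.shape).astype(pred.dtype)


@dataclass(frozen=True)
class SplitPlan:
    train: tuple
    val: tuple
    test: tuple


def split_by_cube(cube_ids: Sequence, n_train: int, n_val: int, seed: int = 0) -> SplitPlan:
    """Randomly assign whole cubes to train/val; the remainder is the test set."""
    ids = list(cube_ids)
    if n_train + n_val > len(ids):
        raise ValueError(
            f"cannot draw {n_train} train + {n_val} val cubes from {len(ids)}")
    order = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    return SplitPlan(
        train=tuple(shuffled[:n_train]),
        val=tuple(shuffled[n_train:n_train + n_val]),
        test=tuple(shuffled[n_train + n_val:]),
    )


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 10
    lr0: float = 0.001
    momentum: float = 0.9            # Nesterov momentum coefficient
    plateau_factor: float = 0.3
    plateau_patience: int = 40
    early_stop_patience: int = 80
    max_epochs: int = 500
    warmup_epochs: int = 0           # linear ramp from lr0/10 to lr0
    grad_clip: float | None = None   # global gradient-norm ceiling
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.early_stop_patience < self.plateau_patience:
            raise ValueError("early_stop_patience must be >= plateau_patience")
        if self.grad_clip is not None and self.grad_clip <= 0:
            raise ValueError("grad_clip must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = 0              # 1-based index of the best-validation epoch
    stop_reason: str = ""

    def to_dict(self) -> dict:
        return {"train_loss": self.train_loss, "val_loss": self.val_loss,
                "lr": self.lr, "best_epoch": self.best_epoch,
                "stop_reason": self.stop_reason}


@dataclass(frozen=True)
class SegmentationDataset:
    """Aligned (image, mask) slice pairs already split at cube level."""

    train_pairs: tuple
    val_pairs: tuple


def dataset_from_cubes(train_cubes: Sequence, val_cubes: Sequence) -> SegmentationDataset:
    """Flatten lists of ``(volume, mask)`` cubes (or PhantomCube) into slice pairs."""
    def pairs(cubes):
        out = []
        for c in cubes:
            vol, msk = (c.volume, c.mask) if hasattr(c, "volume") else c
            out.extend((vol[i], msk[i]) for i in range(vol.shape[0]))
        return tuple(out)
    return SegmentationDataset(pairs(train_cubes), pairs(val_cubes))


def _forward_loss(model: UNet, images: list[np.ndarray], masks: list[np.ndarray],
                  training: bool) -> tuple[float, np.ndarray | None]:
    x, _ = prepare_batch(np.stack([np.asarray(i, dtype=np.float32) for i in images]),
                         model.input_size)
    if model.input_size is not None:
        tgt = np.stack([resize2d(np.asarray(m, dtype=np.float32), x.shape[2:], order=0)
                        for m in masks])
    else:
        tgt = np.stack([np.asarray(m, dtype=np.float32) for m in masks])
        ph, pw = x.shape[2] - tgt.shape[1], x.shape[3] - tgt.shape[2]
        if ph or pw:
            tgt = np.pad(tgt, ((0, 0), (0, ph), (0, pw)))
    prob = model.forward(x, training=training)
    loss, grad = _smooth_dice_loss_grad(prob, tgt)
    return loss, (grad if training else None)


def evaluate_loss(model: UNet, pairs: Sequence, batch_size: int = 10) -> float:
    """Mean Smooth-Dice validation loss over slice pairs (no augmentation)."""
    losses = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        loss, _ = _forward_loss(model, [p[0] for p in chunk], [p[1] for p in chunk],
                                training=False)
        losses.append((loss, len(chunk)))
    total = sum(n for _, n in losses)
    return sum(l * n for l, n in losses) / total


def train_model(model: UNet, dataset: SegmentationDataset,
                aug: AugmentConfig | None = None,
                cfg: TrainConfig | None = None,
                validation_fn: Callable[[UNet, int], float] | None = None,
                ) -> tuple[UNet, TrainHistory]:
    """Train ``model`` with the reference optimization schedule.

    ``validation_fn(model, epoch) -> float`` overrides the validation-loss
    computation (used e.g. to audit the plateau/early-stop logic with a
    scripted signal); by default the Smooth Dice loss is evaluated on the
    validation slices without augmentation.

    Returns the best-validation snapshot of the model and the history.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    if not dataset.train_pairs or (validation_fn is None and not dataset.val_pairs):
        raise ValueError("training requires non-empty train and validation sets")
    rng = np.random.default_rng(cfg.seed)
    aug_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    optimizer = SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum, nesterov=True)
    history = TrainHistory()
    best_val = np.inf
    best_state: dict | None = None
    stall = 0
    lr = cfg.lr0

    n_train = len(dataset.train_pairs)
    for epoch in range(1, cfg.max_epochs + 1):
        if epoch <= cfg.warmup_epochs:
            # batch statistics are unreliable at the start; ramp the rate up
            optimizer.lr = lr * (0.1 + 0.9 * epoch / (cfg.warmup_epochs + 1))
        else:
            optimizer.lr = lr
        order = rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train, cfg.batch_size):
            batch = [dataset.train_pairs[i] for i in order[start:start + cfg.batch_size]]
            if aug is not None:
                batch = [augment_pair(img, msk, aug, rng=aug_rng) for img, msk in batch]
            loss, grad = _forward_loss(model, [b[0] for b in batch],
                                       [b[1] for b in batch], training=True)
            model.backward(grad)
            grads = model.gradients()
            if cfg.grad_clip is not None:
                norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
                if norm > cfg.grad_clip:
                    scale = cfg.grad_clip / norm
                    grads = {k: g * scale for k, g in grads.items()}
            optimizer.step(grads)
            epoch_losses.append(loss)
        train_loss = float(np.mean(epoch_losses)) if epoch_losses else np.nan

        if validation_fn is not None:
            val_loss = float(validation_fn(model, epoch))
        else:
            val_loss = evaluate_loss(model, dataset.val_pairs, cfg.batch_size)

        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.lr.append(optimizer.lr)
        logger.info("epoch %d: train %.5f val %.5f lr %.2e", epoch, train_loss, val_loss, lr)

        if val_loss < best_val:
            best_val = val_loss
            history.best_epoch = epoch
            best_state = copy.deepcopy(model.state_dict())
            stall = 0
        else:
            stall += 1
            if stall % cfg.plateau_patience == 0:
                lr *= cfg.plateau_factor
                optimizer.lr = lr
                logger.info("validation plateau: lr reduced to %.2e", lr)
            if stall >= cfg.early_stop_patience:
                history.stop_reason = "early_stopping"
                break
    else:
        history.stop_reason = "max_epochs"

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history
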