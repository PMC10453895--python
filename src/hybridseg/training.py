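"""Dataset splitting, SGD training with early stopping, and fine-tuning.

Training follows the classic recipe: minibatch stochastic gradient descent
with momentum 0.9, weight decay 5e-4, learning rate 1e-3, batch size 16,
up to 100 epochs, on the combined cross-entropy + soft-Dice loss, with
early stopping on validation loss and best-weights restoration.
Fine-tuning (used after fusing handcrafted features into a trained
backbone) reruns the same loop with the learning rate divided by 10 and an
epoch cap of 50.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .losses_metrics import confusion_counts, region_binarize, segmentation_metrics
from .model import SegmentationCNN, forward_predict
from .nn import Var


@dataclass
class TrainConfig:
    momentum: float = 0.9
    learning_rate: float = 0.0010
    weight_decay: float = 0.0005
    batch_size: int = 16
    epochs: int = 100
    patience: int = 10
    seed: int = 0
    dice_epsilon: float = 1e-6

    def validate(self) -> None:
        if min(self.learning_rate, self.batch_size) <= 0 or self.momentum < 0:
            raise ValueError("invalid training config")
        if self.weight_decay < 0 or self.epochs < 0 or self.patience < 1:
            raise ValueError("invalid training config")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    learning_rate: float = 0.0
    config: TrainConfig | None = None


class EarlyStopper:
    """Stop when the monitored loss fails to improve for ``patience`` epochs."""

    def __init__(self, patience: int, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = 0
        self.bad_epochs = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's loss; return True when training should stop."""
        self.epoch += 1
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = self.epoch
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def split_dataset(case_ids, train_fraction: float = 0.7, seed: int = 0):
    """Seeded shuffle-split into disjoint, exhaustive train/test id lists.

    Train size is round(fraction * n): 285 ids at 0.70 give the 200/85
    split convention.
    """
    ids = list(case_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("non-unique cases")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    order = np.random.default_rng(seed).permutation(len(ids))
    n_train = int(np.floor(train_fraction * len(ids) + 0.5))
    train = [ids[i] for i in order[:n_train]]
    test = [ids[i] for i in order[n_train:]]
    return train, test


def _as_arrays(dataset):
    """Dataset of (slice, mask[, feature-stack]) tuples -> stacked arrays."""
    imgs, masks, feats = [], [], []
    has_feats = None
    for item in dataset:
        sl, mk = item[0], item[1]
        px = sl.pixels if hasattr(sl, "pixels") else np.asarray(sl)
        lb = mk.labels if hasattr(mk, "labels") else np.asarray(mk)
        imgs.append(np.asarray(px, dtype=np.float32))
        masks.append(np.asarray(lb))
        if len(item) > 2 and item[2] is not None:
            ft = item[2].channels if hasattr(item[2], "channels") else item[2]
            feats.append(np.asarray(ft, dtype=np.float32))
            has_feats = True
        elif has_feats:
            raise ValueError("feature stacks present for only part of the dataset")
    x = np.stack(imgs)
    y = np.stack(masks).astype(np.int64)
    f = np.stack(feats) if feats else None
    return x, y, f


def _epoch_loss(model, x, y, f, batch_size, dice_epsilon):
    total, n = 0.0, 0
    for i in range(0, x.shape[0], batch_size):
        fb = None if f is None else f[i : i + batch_size]
        yb = y[i : i + batch_size]
        logits = model.forward_graph(x[i : i + batch_size], fb)
        _, ce, dice = nn.combined_loss_op(logits, yb, epsilon=dice_epsilon)
        total += (ce + dice) * yb.shape[0]
        n += yb.shape[0]
    return total / max(n, 1)


def _mean_region_dice(model, x, y, f, region="WT", batch_size=16):
    pred = forward_predict(model, x, f, batch_size=batch_size)
    vals = []
    for p, t in zip(pred.labels, y):
        counts = confusion_counts(region_binarize(p, region), region_binarize(t, region))
        vals.append(segmentation_metrics(counts)["dice"])
    return float(np.mean(vals))


def sgd_step(model: SegmentationCNN, grads, velocity, config: TrainConfig) -> None:
    """One SGD-with-momentum update; weight decay on weights, not biases."""
    for key, p in model.params.items():
        g = grads[key]
        if config.weight_decay and key.endswith(".w"):
            g = g + config.weight_decay * p
        velocity[key] = config.momentum * velocity[key] - config.learning_rate * g
        p += velocity[key]


def train_model(
    model: SegmentationCNN,
    train_set,
    val_set,
    config: TrainConfig | None = None,
    val_loss_fn=None,
) -> tuple[SegmentationCNN, TrainHistory]:
    """Minibatch SGD training with early stopping and best-weight restore.

    ``train_set`` / ``val_set`` are sequences of (slice, mask) or
    (slice, mask, feature_stack) tuples.  ``val_loss_fn`` (model -> float)
    can replace the validation pass, which is how the early-stopping rule
    is exercised in isolation.  Deterministic given ``config.seed``.
    """
    config = config or TrainConfig()
    config.validate()
    history = TrainHistory(learning_rate=config.learning_rate, config=config)
    if config.epochs == 0:
        return model, history
    if not len(train_set):
        raise ValueError("no data: empty training set")

    x, y, f = _as_arrays(train_set)
    if val_loss_fn is None:
        if not len(val_set):
            raise ValueError("no data: empty validation set")
        xv, yv, fv = _as_arrays(val_set)
        def val_loss_fn(m):
            return _epoch_loss(m, xv, yv, fv, config.batch_size, config.dice_epsilon)

    rng = np.random.default_rng(config.seed)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    stopper = EarlyStopper(config.patience)
    best_state = model.state_dict()

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(x.shape[0])
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            fb = None if f is None else f[idx]
            pvars = {k: Var(v) for k, v in model.params.items()}
            logits = model.forward_graph(x[idx], fb, pvars=pvars)
            loss, ce, dice = nn.combined_loss_op(
                logits, y[idx], epsilon=config.dice_epsilon
            )
            if not np.isfinite(ce + dice):
                history.stopped_epoch = epoch
                raise RuntimeError(f"diverged at epoch {epoch}; history: "
                                   f"{history.train_loss}")
            nn.backward(loss)
            grads = {k: pvars[k].grad for k in model.params}
            sgd_step(model, grads, velocity, config)
            epoch_losses.append(ce + dice)
        history.train_loss.append(float(np.mean(epoch_losses)))
        vloss = float(val_loss_fn(model))
        history.val_loss.append(vloss)
        stop = stopper.update(vloss)
        if stopper.best_epoch == stopper.epoch:
            best_state = model.state_dict()
        if stop:
            break
    history.stopped_epoch = stopper.epoch
    history.best_epoch = stopper.best_epoch
    model.load_state_dict(best_state)
    return model, history


def finetune_model(
    model: SegmentationCNN,
    train_set,
    val_set,
    base_config: TrainConfig | None = None,
    epochs: int | None = None,
) -> tuple[SegmentationCNN, TrainHistory]:
    """Fine-tune with the learning rate reduced by a factor of 10, <= 50 epochs."""
    base_config = base_config or TrainConfig()
    cfg = replace(
        base_config,
        learning_rate=base_config.learning_rate / 10.0,
        epochs=min(50, base_config.epochs) if epochs is None else epochs,
    )
    return train_model(model, train_set, val_set, cfg)


def evaluate_training_dice(model, dataset, region="WT", batch_size=16) -> float:
    """Mean per-case Dice of a region over a dataset (convenience wrapper)."""
    x, y, f = _as_arrays(dataset)
    return _mean_region_dice(model, x, y, f, region=region, batch_size=batch_size)
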