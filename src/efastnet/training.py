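"""Mini-batch training with validation-patience early stopping.

The stopping rule: track the best validation loss seen so far; if it fails
to improve for ``patience`` consecutive epochs, halt and restore the weights
of the best epoch.  Improvement means strictly lower loss (delta 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import ModelHandle, class_probabilities, final_activation
from .preprocess import AugmentPolicy, augment_pixels
from . import nn

__all__ = [
    "ImageDataset",
    "EarlyStopping",
    "TrainingHistory",
    "train_model",
    "evaluate_accuracy",
    "batch_loss_and_grad",
]

_EPS = 1e-9


@dataclass
class ImageDataset:
    """Images (N, H, W) in [0, 1] with integer labels (1 = positive).

    ``subjects`` records which subjects contributed frames, for leakage
    audits across splits.
    """

    X: np.ndarray
    y: np.ndarray
    subjects: frozenset[str] = frozenset()

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")

    def __len__(self) -> int:
        return len(self.X)

    @classmethod
    def from_frames(cls, frames) -> "ImageDataset":
        X = np.stack([f.pixels for f in frames])
        y = np.array([1 if f.label == "positive" else 0 for f in frames])
        return cls(X, y, frozenset(f.subject_id for f in frames))


class EarlyStopping:
    """Validation-patience controller, usable on any scripted loss sequence."""

    def __init__(self, patience: int = 5):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.epochs_since_best = 0
        self.epoch = 0

    def update(self, val_loss: float) -> bool:
        """Record one epoch's validation loss; True means stop now.

        Returns True once ``patience`` consecutive epochs have failed to
        improve on the best loss so far.
        """
        self.epoch += 1
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = self.epoch
            self.epochs_since_best = 0
            return False
        self.epochs_since_best += 1
        return self.epochs_since_best >= self.patience

    @property
    def improved(self) -> bool:
        return self.epochs_since_best == 0


@dataclass
class TrainingHistory:
    val_losses: list[float] = field(default_factory=list)
    epochs_run: int = 0
    best_epoch: int = 0
    best_val_loss: float = np.inf
    failed: bool = False


def batch_loss_and_grad(scores: np.ndarray, y: np.ndarray,
                        activator: str) -> tuple[float, np.ndarray]:
    """Cross-entropy on the head's class probabilities, plus d(loss)/d(scores).

    softmax head: standard softmax cross-entropy.  softplus head: the two
    softplus outputs are L1-normalized into probabilities; the gradient is
    propagated through the normalization and the softplus analytically.
    """
    n = len(y)
    onehot = np.zeros((n, 2), dtype=np.float64)
    onehot[np.arange(n), y] = 1.0
    if activator == "softmax":
        p = class_probabilities(scores, "softmax")
        loss = -np.mean(np.log(p[np.arange(n), y] + _EPS))
        grad = (p - onehot) / n
    else:
        s = final_activation(scores, "softplus")  # (n, 2), positive
        tot = s.sum(axis=1, keepdims=True)
        p = s / tot
        loss = -np.mean(np.log(p[np.arange(n), y] + _EPS))
        # dL/ds_i = 1/S - delta_{i=y}/s_y ; ds/da = sigmoid(a)
        dL_ds = 1.0 / tot - onehot / (s + _EPS)
        sig = 1.0 / (1.0 + np.exp(-np.asarray(scores, dtype=np.float64)))
        grad = dL_ds * sig / n
    return float(loss), grad.astype(np.float32)


def _dataset_loss(handle: ModelHandle, ds: ImageDataset, batch: int = 128) -> float:
    losses, weights = [], []
    for i in range(0, len(ds), batch):
        xb = ds.X[i:i + batch][:, None]
        scores = handle.net.forward(xb, train=False)
        if not np.isfinite(scores).all():
            return float("nan")
        loss, _ = batch_loss_and_grad(scores, ds.y[i:i + batch], handle.activator)
        losses.append(loss)
        weights.append(len(xb))
    return float(np.average(losses, weights=weights))


def evaluate_accuracy(handle: ModelHandle, ds: ImageDataset,
                      batch: int = 128) -> float:
    correct = 0
    for i in range(0, len(ds), batch):
        pred = handle.predict_labels(ds.X[i:i + batch])
        correct += int((pred == ds.y[i:i + batch]).sum())
    return correct / max(len(ds), 1)


def train_model(handle: ModelHandle, train: ImageDataset, val: ImageDataset,
                optimizer_name: str, learning_rate: float, batch_size: int,
                rng: np.random.Generator, max_epochs: int = 100,
                patience: int = 5,
                augment: AugmentPolicy | None = None) -> TrainingHistory:
    """Train in place with early stopping; best-epoch weights are restored.

    A non-finite training or validation loss aborts the run and marks the
    history ``failed`` (the caller records it as a zero-accuracy run).
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation datasets must be non-empty")
    opt = nn.make_optimizer(optimizer_name, learning_rate)
    stopper = EarlyStopping(patience)
    hist = TrainingHistory()
    best_weights = handle.net.get_weights()
    n = len(train)
    for _ in range(max_epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            xb = train.X[idx]
            if augment is not None and not augment.is_identity:
                xb = np.stack([augment_pixels(x, augment, rng) for x in xb])
            scores = handle.net.forward(xb[:, None], train=True)
            if not np.isfinite(scores).all():
                hist.failed = True
                hist.epochs_run = stopper.epoch + 1
                handle.net.set_weights(best_weights)
                return hist
            loss, grad = batch_loss_and_grad(scores, train.y[idx], handle.activator)
            if not np.isfinite(loss):
                hist.failed = True
                hist.epochs_run = stopper.epoch + 1
                handle.net.set_weights(best_weights)
                return hist
            handle.net.backward(grad)
            opt.step(handle.net)
        val_loss = _dataset_loss(handle, val)
        stop = stopper.update(val_loss)
        hist.val_losses.append(val_loss)
        hist.epochs_run = stopper.epoch
        if not np.isfinite(val_loss):
            hist.failed = True
            break
        if stopper.improved:
            best_weights = handle.net.get_weights()
        if stop:
            break
    hist.best_epoch = stopper.best_epoch
    hist.best_val_loss = float(stopper.best_loss)
    handle.net.set_weights(best_weights)
    return hist
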