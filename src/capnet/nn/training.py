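"""Training loop: cross-entropy loss, SGD with momentum, best-val checkpoint.

Default hyperparameters follow the reference recipe (batch 256, SGD with
learning rate 0.001 and momentum 0.9, 40 epochs, no dropout).  The loop is
pure NumPy and therefore exactly reproducible: identical seeds, data, and
order give bit-identical histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from capnet.nn.layers import Module
from capnet.nn.models import load_state_dict, state_dict

__all__ = ["TrainConfig", "TrainedModel", "train", "predict", "softmax"]

LABELS = ("B", "A")  # logit index 0 = B (background), 1 = A (activation)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters; defaults match the reference training recipe."""

    batch_size: int = 256
    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 40
    seed: int = 0
    model_variant: str = "resnet18_gray_binary"
    shuffle: bool = True


@dataclass
class TrainedModel:
    """A trained network with its history and config snapshot.

    ``history`` has one entry per epoch with train/val loss and accuracy;
    the model weights are those of the epoch with the best validation
    accuracy (ties resolved to the earliest such epoch).
    """

    model: Module
    history: list[dict] = field(default_factory=list)
    config: TrainConfig = field(default_factory=TrainConfig)
    best_epoch: int = -1


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _as_batches(n: int, batch_size: int, order: np.ndarray):
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _xent_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    p = softmax(logits)
    n = len(y)
    loss = -float(np.mean(np.log(np.clip(p[np.arange(n), y], 1e-12, None))))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


def _eval_pass(model: Module, X: np.ndarray, y: np.ndarray, batch_size: int):
    losses, correct, total = [], 0, 0
    for i in range(0, len(X), batch_size):
        xb = X[i : i + batch_size, None, :, :]
        logits = model.forward(xb.astype(np.float32), train=False)
        loss, _ = _xent_and_grad(logits, y[i : i + batch_size])
        losses.append(loss * len(xb))
        pred = _decide(softmax(logits))
        correct += int(np.sum(pred == y[i : i + batch_size]))
        total += len(xb)
    return float(np.sum(losses) / total), correct / total


def _decide(probs: np.ndarray) -> np.ndarray:
    """Class decision with ties broken toward B (index 0)."""
    return (probs[:, 1] > probs[:, 0]).astype(int)


def train(
    model: Module,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray] | None,
    config: TrainConfig,
    augment_fn=None,
) -> TrainedModel:
    """Minimize cross-entropy with SGD + momentum; keep the best-val epoch.

    ``train_set``/``val_set`` are ``(images, labels)`` with images of shape
    (n, n_freq, n_time), already normalized, and integer labels (0 = B,
    1 = A).  ``augment_fn(batch_images, rng) -> images`` is applied to each
    training batch on the fly.  Without a validation set the final epoch's
    weights are kept.
    """
    X, y = train_set
    if len(X) == 0:
        raise ValueError("empty training set")
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(config.seed)
    trained = TrainedModel(model=model, config=config)
    best_acc, best_state = -1.0, None

    for epoch in range(config.epochs):
        order = rng.permutation(len(X)) if config.shuffle else np.arange(len(X))
        epoch_loss, correct = 0.0, 0
        for idx in _as_batches(len(X), config.batch_size, order):
            xb = X[idx].astype(np.float32)
            if augment_fn is not None:
                xb = augment_fn(xb, rng)
            logits = model.forward(xb[:, None, :, :], train=True)
            loss, dlogits = _xent_and_grad(logits, y[idx])
            epoch_loss += loss * len(idx)
            correct += int(np.sum(_decide(softmax(logits)) == y[idx]))
            for p in model.params():
                p.grad[...] = 0.0
            model.backward(dlogits)
            for p in model.params():
                p.velocity = config.momentum * p.velocity + p.grad
                p.data -= config.learning_rate * p.velocity

        entry = {
            "epoch": epoch,
            "train_loss": epoch_loss / len(X),
            "train_acc": correct / len(X),
        }
        if val_set is not None and len(val_set[0]):
            entry["val_loss"], entry["val_acc"] = _eval_pass(
                model, val_set[0], np.asarray(val_set[1], dtype=int), config.batch_size
            )
            if entry["val_acc"] > best_acc:
                best_acc, best_state = entry["val_acc"], state_dict(model)
                trained.best_epoch = epoch
        trained.history.append(entry)

    if best_state is not None:
        load_state_dict(model, best_state)
    else:
        trained.best_epoch = config.epochs - 1
    return trained


def predict(
    model: Module, images: np.ndarray, batch_size: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Per-image class probabilities and labels ('A'/'B'), ties going to B."""
    probs = []
    for i in range(0, len(images), batch_size):
        xb = np.asarray(images[i : i + batch_size], dtype=np.float32)[:, None, :, :]
        probs.append(softmax(model.forward(xb, train=False)))
    p = np.concatenate(probs) if probs else np.zeros((0, 2))
    labels = np.where(_decide(p) == 1, "A", "B")
    return p, labels
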