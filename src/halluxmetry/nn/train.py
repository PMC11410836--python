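"""RMSE-loss training loop with periodic validation and early stopping.

The protocol mirrors the fixed hyperparameters used for the full-scale
radiograph model: Adam, at most 12 epochs, minibatch 7, initial learning
rate 1e-4, validation every 200 iterations, and early stopping after 10
consecutive validations without improvement; the best-validation weights
are restored at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ..errors import ConfigurationError
from .unet import UNet

Array = np.ndarray


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    max_epochs: int = 12
    minibatch_size: int = 7
    initial_learning_rate: float = 1e-4
    validation_frequency: int = 200
    validation_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ConfigurationError("only the Adam optimizer is supported")
        if min(self.max_epochs, self.minibatch_size, self.validation_frequency,
               self.validation_patience) < 1 or self.initial_learning_rate <= 0:
            raise ConfigurationError("training parameters must be positive")


@dataclass
class TrainHistory:
    """Per-iteration training loss and per-validation loss trace."""

    iterations: List[int] = field(default_factory=list)
    train_rmse: List[float] = field(default_factory=list)
    val_iterations: List[int] = field(default_factory=list)
    val_rmse: List[float] = field(default_factory=list)
    best_val_rmse: float = float("inf")
    best_iteration: int = -1
    stopped_early: bool = False


def rmse_loss(predicted, target) -> float:
    """Root-mean-square error over all pixels and channels."""
    p = np.asarray(getattr(predicted, "values", predicted), dtype=np.float64)
    t = np.asarray(getattr(target, "values", target), dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def _as_batches(images: Array, targets: Array, order: Array,
                batch_size: int):
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        yield images[idx], targets[idx]


def _eval_rmse(net: UNet, images: Array, targets: Array, batch_size: int) -> float:
    se, n = 0.0, 0
    for start in range(0, len(images), batch_size):
        x = images[start:start + batch_size]
        t = targets[start:start + batch_size]
        out = net.forward(x[:, None, :, :])
        se += float(((out - t) ** 2).sum())
        n += out.size
    return float(np.sqrt(se / n))


def _stack_dataset(dataset: Sequence[Tuple[Array, Array]]) -> Tuple[Array, Array]:
    images = np.stack([np.asarray(img, dtype=np.float64) for img, _ in dataset])
    targets = np.stack([
        np.asarray(getattr(t, "values", t), dtype=np.float64).transpose(2, 0, 1)
        for _, t in dataset])
    return images, targets


def train(network: UNet, train_set: Sequence[Tuple[Array, Array]],
          val_set: Optional[Sequence[Tuple[Array, Array]]] = None,
          config: TrainConfig = TrainConfig()) -> TrainHistory:
    """Fit the network on (image, heatmap-stack) pairs.

    ``train_set`` / ``val_set`` are sequences of ``(image, target)`` where
    ``image`` is a standardized (S, S) array and ``target`` an (S, S, 6)
    heatmap stack (or :class:`~halluxmetry.heatmaps.HeatmapStack`).  Returns
    the training history; the network ends at the best-validation weights
    (or the final weights when no validation set is given).
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    images, targets = _stack_dataset(train_set)
    if val_set is not None and len(val_set) > 0:
        val_images, val_targets = _stack_dataset(val_set)
    else:
        val_images = val_targets = None

    rng = np.random.default_rng(config.seed)
    opt = network.make_optimizer(config.initial_learning_rate)
    history = TrainHistory()
    best_weights = None
    bad_validations = 0
    iteration = 0

    for _epoch in range(config.max_epochs):
        order = rng.permutation(len(images))
        for xb, tb in _as_batches(images, targets, order, config.minibatch_size):
            out = network.forward(xb[:, None, :, :])
            diff = out - tb
            loss = float(np.sqrt(np.mean(diff ** 2)))
            # d(RMSE)/d(out) = diff / (numel * RMSE)
            grad = diff / (diff.size * max(loss, 1e-12))
            network.backward(grad)
            opt.step()
            iteration += 1
            history.iterations.append(iteration)
            history.train_rmse.append(loss)

            if val_images is not None and iteration % config.validation_frequency == 0:
                val = _eval_rmse(network, val_images, val_targets,
                                 config.minibatch_size)
                history.val_iterations.append(iteration)
                history.val_rmse.append(val)
                if val < history.best_val_rmse:
                    history.best_val_rmse = val
                    history.best_iteration = iteration
                    best_weights = network.get_weights()
                    bad_validations = 0
                else:
                    bad_validations += 1
                    if bad_validations >= config.validation_patience:
                        history.stopped_early = True
                        if best_weights is not None:
                            network.set_weights(best_weights)
                        return history

    # end of training: restore the best validation checkpoint if one exists
    if val_images is not None:
        val = _eval_rmse(network, val_images, val_targets, config.minibatch_size)
        history.val_iterations.append(iteration)
        history.val_rmse.append(val)
        if val < history.best_val_rmse:
            history.best_val_rmse = val
            history.best_iteration = iteration
            best_weights = network.get_weights()
    if best_weights is not None:
        network.set_weights(best_weights)
    return history
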