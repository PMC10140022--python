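"""Training loop: Adam, shuffled mini-batches, early stopping, checkpointing.

Defaults mirror the reference training protocol for the full-size model:
learning rate 1e-3, moment decays (0.9, 0.999), batch size 48, at most
1000 epochs, early stop after 75 epochs without a strictly lower
validation loss, best-validation weights checkpointed.  Desk-scale runs
override epochs/patience explicitly.

"No improvement" means the validation head loss (MSE or binary
cross-entropy, evaluated in inference mode, without the L2 term) is not
strictly lower than the best value so far, compared at full float
precision.  The recorded history has columns epoch / train_loss (the
optimized objective including L2) / val_loss (head loss).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CNN3d

__all__ = ["TrainConfig", "train"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    moment_decays: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 48
    max_epochs: int = 1000
    early_stop_patience: int = 75
    checkpoint_best: bool = True
    seed: int = 0
    adam_eps: float = 1e-8
    # Start the regression head's output bias at the training-target mean so
    # the output ReLU begins in its active region (a zero start can leave the
    # whole head in the dead zone with zero gradient).
    init_output_bias: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("early_stop_patience must be < max_epochs")


class _Adam:
    def __init__(self, params, cfg: TrainConfig):
        self.params = params
        self.lr = cfg.learning_rate
        self.b1, self.b2 = cfg.moment_decays
        self.eps = cfg.adam_eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(
    model: CNN3d,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    verbose: bool = False,
) -> CNN3d:
    """Train in place; returns the model with best-validation weights restored.

    Raises on empty splits and on non-finite losses (with the epoch index).
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("empty training or validation split")
    y_train = np.asarray(y_train, dtype=np.float32)
    y_val = np.asarray(y_val, dtype=np.float32)
    rng = np.random.default_rng(config.seed)
    if config.init_output_bias and model.config.head == "regression":
        model.layers[-1].bias.value[...] = float(np.mean(y_train))
    opt = _Adam(model.parameters, config)

    best_val = np.inf
    best_epoch = -1
    best_weights = model.get_weights() if config.checkpoint_best else None
    rows = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            objective, _ = model.loss_and_grads(x_train[idx], y_train[idx])
            if not np.isfinite(objective):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}"
                )
            epoch_losses.append(objective)
            opt.step()
        val_loss = model.data_loss(x_val, y_val, batch_size=config.batch_size)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
             "val_loss": val_loss}
        )
        if verbose:
            print(f"epoch {epoch:4d}  train {rows[-1]['train_loss']:.4f}  "
                  f"val {val_loss:.4f}")
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            if config.checkpoint_best:
                best_weights = model.get_weights()
        elif epoch - best_epoch >= config.early_stop_patience:
            break

    if config.checkpoint_best and best_weights is not None:
        model.set_weights(best_weights)
    model.training_history = pd.DataFrame(rows)
    model.best_epoch = int(best_epoch)
    return model
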