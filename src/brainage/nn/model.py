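"""The five-block 3D CNN for brain phenotype prediction, size-configurable.

Architecture (per block): 3x3x3 conv (stride 1) -> ReLU -> 3x3x3 conv
(stride 1) -> batch norm -> ReLU -> 2x2x2 max pool (stride 2).  Channel
width starts at ``base_channels`` and doubles after every pooling stage;
a single fully connected layer maps the flattened final block to one
output.  Heads: regression (ReLU output, MSE loss) or binary
classification (sigmoid output, binary cross-entropy loss).  Every
convolutional and fully connected kernel carries an L2 penalty
``l2_lambda * sum(w^2)`` added to the data loss.

The reference configuration is 128^3 x 2-channel input, 5 blocks, base
width 8 (final feature grid 4^3 x 128); desk-scale instances (e.g. 16^3,
2 blocks, base 4) train in minutes on one CPU and are used throughout
the tests and the synthetic study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .layers import BatchNorm3d, Conv3d, Dense, Flatten, MaxPool3d, Parameter, ReLU

__all__ = ["ArchitectureConfig", "CNN3d", "build_model", "save_model", "load_model"]


@dataclass
class ArchitectureConfig:
    input_shape: tuple[int, int, int] = (128, 128, 128)
    in_channels: int = 2
    n_blocks: int = 5
    base_channels: int = 8
    l2_lambda: float = 1e-3
    head: str = "regression"  # "regression" | "classification"

    def __post_init__(self) -> None:
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.head not in ("regression", "classification"):
            raise ValueError(f"unknown head {self.head!r}")
        div = 2**self.n_blocks
        for ax, s in enumerate(self.input_shape):
            if s % div:
                raise ValueError(
                    f"input axis {ax} size {s} is not divisible by 2^{self.n_blocks}"
                )

    @property
    def final_spatial(self) -> tuple[int, int, int]:
        div = 2**self.n_blocks
        return tuple(s // div for s in self.input_shape)

    @property
    def final_channels(self) -> int:
        return self.base_channels * 2 ** (self.n_blocks - 1)

    @property
    def flat_features(self) -> int:
        return self.final_channels * int(np.prod(self.final_spatial))


class CNN3d:
    """Layer stack + head; doubles as the "trained model" container.

    After :func:`brainage.nn.train.train` the instance carries
    ``training_history`` (per-epoch losses) and ``best_epoch`` (the
    checkpointed epoch attaining the minimum validation loss).
    """

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        layers: list = []
        c_in = config.in_channels
        for b in range(config.n_blocks):
            c_out = config.base_channels * 2**b
            layers.append(Conv3d(c_in, c_out, rng, name=f"block{b+1}.conv1"))
            layers.append(ReLU())
            layers.append(Conv3d(c_out, c_out, rng, name=f"block{b+1}.conv2"))
            layers.append(BatchNorm3d(c_out, name=f"block{b+1}.bn"))
            layers.append(ReLU())
            layers.append(MaxPool3d())
            c_in = c_out
        layers.append(Flatten())
        layers.append(Dense(config.flat_features, 1, rng))
        self.layers = layers
        self.training_history = None  # filled by train()
        self.best_epoch: int | None = None

    # -- parameters ---------------------------------------------------------

    @property
    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.params]

    def get_weights(self) -> list[np.ndarray]:
        ws = [p.value.copy() for p in self.parameters]
        for layer in self.layers:
            if isinstance(layer, BatchNorm3d):
                ws.append(layer.running_mean.copy())
                ws.append(layer.running_var.copy())
        return ws

    def set_weights(self, ws: list[np.ndarray]) -> None:
        n = len(self.parameters)
        for p, w in zip(self.parameters, ws[:n]):
            p.value[...] = w
        extra = iter(ws[n:])
        for layer in self.layers:
            if isinstance(layer, BatchNorm3d):
                layer.running_mean[...] = next(extra)
                layer.running_var[...] = next(extra)

    def kernel_sq_norm(self) -> float:
        return float(
            sum(np.sum(p.value.astype(np.float64) ** 2)
                for p in self.parameters if p.kernel)
        )

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        # float64 inputs stay float64 (used for high-precision gradient
        # verification); everything else runs in float32
        dtype = np.float64 if np.asarray(x).dtype == np.float64 else np.float32
        x = np.asarray(x, dtype=dtype)
        expect = (self.config.in_channels, *self.config.input_shape)
        if x.ndim == 4:
            x = x[None]
        if x.shape[1:] != expect:
            raise ValueError(f"input shape {x.shape[1:]} != expected {expect}")
        return x

    def forward_logits(self, x: np.ndarray, training: bool) -> np.ndarray:
        """Pre-activation output, shape (n,)."""
        out = x
        for layer in self.layers:
            out = layer.forward(out, training)
        return out[:, 0]

    def _activate(self, z: np.ndarray) -> np.ndarray:
        if self.config.head == "regression":
            return np.maximum(z, 0.0)
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, x: np.ndarray, batch_size: int = 48) -> np.ndarray:
        """Per-subject estimates in inference mode (deterministic for fixed
        weights); classification estimates lie in [0, 1]."""
        x = self._check_input(x)
        outs = []
        for i in range(0, x.shape[0], batch_size):
            z = self.forward_logits(x[i : i + batch_size], training=False)
            outs.append(self._activate(z))
        out = np.concatenate(outs).astype(np.float64)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite prediction")
        return out

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, training: bool = True
                       ) -> tuple[float, float]:
        """Compute loss and fill parameter gradients.

        Returns ``(objective, data_loss)`` where objective = data loss +
        L2 penalty; parameter ``grad`` buffers include the penalty term.
        """
        x = self._check_input(x)
        y = np.asarray(y, dtype=np.float32)
        n = x.shape[0]
        z = self.forward_logits(x, training)
        yhat = self._activate(z)
        if self.config.head == "regression":
            data_loss = float(np.mean((yhat - y) ** 2))
            dz = (2.0 / n) * (yhat - y) * (z > 0)
        else:
            p = np.clip(yhat, 1e-7, 1 - 1e-7)
            data_loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
            dz = (yhat - y) / n
        dout = dz[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        lam = self.config.l2_lambda
        for p in self.parameters:
            if p.kernel:
                p.grad += 2.0 * lam * p.value
        objective = data_loss + lam * self.kernel_sq_norm()
        return objective, data_loss

    def data_loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 48) -> float:
        """Head loss (MSE or BCE) in inference mode, without the L2 term."""
        x = self._check_input(x)
        y = np.asarray(y, dtype=np.float64)
        yhat = self.predict(x, batch_size=batch_size)
        if self.config.head == "regression":
            return float(np.mean((yhat - y) ** 2))
        p = np.clip(yhat, 1e-7, 1 - 1e-7)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d(prediction)/d(input) in inference mode, per subject.

        Returns an array of the input's shape.  This is the engine behind
        SmoothGrad saliency; it backpropagates through frozen batch-norm
        statistics.
        """
        x = self._check_input(x)
        z = self.forward_logits(x, training=False)
        if self.config.head == "regression":
            dz = (z > 0).astype(np.float32)
        else:
            p = 1.0 / (1.0 + np.exp(-z))
            dz = (p * (1 - p)).astype(np.float32)
        dout = dz[:, None]
        for layer in reversed(self.layers):
            dout = layer.backward(dout, need_param_grads=False)
        return dout


# alias: a trained model is a CNN3d carrying history and checkpointed weights
TrainedModel = CNN3d


def build_model(config: ArchitectureConfig, seed: int = 0) -> CNN3d:
    """Construct an untrained model (fan-in-scaled random init, seeded)."""
    return CNN3d(config, seed=seed)


def save_model(model: CNN3d, path: Path | str) -> None:
    """Single-file checkpoint with the architecture config embedded."""
    path = Path(path)
    cfg = {
        "input_shape": list(model.config.input_shape),
        "in_channels": model.config.in_channels,
        "n_blocks": model.config.n_blocks,
        "base_channels": model.config.base_channels,
        "l2_lambda": model.config.l2_lambda,
        "head": model.config.head,
        "seed": model.seed,
        "best_epoch": model.best_epoch,
    }
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, config=json.dumps(cfg), **arrays)


def load_model(path: Path | str) -> CNN3d:
    with np.load(path, allow_pickle=False) as f:
        cfg = json.loads(str(f["config"]))
        ws = [f[f"w{i}"] for i in range(len(f.files) - 1)]
    config = ArchitectureConfig(
        input_shape=tuple(cfg["input_shape"]),
        in_channels=cfg["in_channels"],
        n_blocks=cfg["n_blocks"],
        base_channels=cfg["base_channels"],
        l2_lambda=cfg["l2_lambda"],
        head=cfg["head"],
    )
    model = CNN3d(config, seed=cfg["seed"])
    model.set_weights(ws)
    model.best_epoch = cfg["best_epoch"]
    return model
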