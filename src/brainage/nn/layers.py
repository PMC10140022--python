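"""NumPy building blocks for the 3D CNN.

Each layer exposes ``forward(x, training)`` and ``backward(dout)``;
``backward`` returns the gradient with respect to the layer input and
fills the ``grad`` buffers of its :class:`Parameter` objects.  All math
is float32; convolutions run as im2col + BLAS matmul, which is the
fastest pure-NumPy route on a single CPU at the grid sizes used here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "Flatten",
    "Dense",
]


class Parameter:
    """A trainable array, its gradient buffer and its L2 eligibility.

    ``kernel=True`` marks weights subject to the L2 penalty (convolution
    and fully connected kernels); biases and batch-norm affine terms are
    excluded, matching the usual "kernel regularizer" convention.
    """

    def __init__(self, value: np.ndarray, kernel: bool, name: str):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.kernel = kernel
        self.name = name


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, D, H, W) -> (N, P, C*k^3) patch matrix with 'same' zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    # win: (N, C, D, H, W, k, k, k) -> (N, D*H*W, C*k^3)
    n, c, d, h, w = x.shape
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, d * h * w, c * k**3)
    return np.ascontiguousarray(cols)


class Conv3d:
    """k x k x k convolution, stride 1, 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3,
                 name: str = "conv"):
        fan_in = c_in * k**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k))
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.weight = Parameter(w, kernel=True, name=f"{name}.weight")
        self.bias = Parameter(np.zeros(c_out), kernel=False, name=f"{name}.bias")
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    @property
    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        cols = _im2col(x, self.k)
        wmat = self.weight.value.reshape(self.c_out, -1).T  # (C*k^3, F)
        out = cols @ wmat + self.bias.value
        self._cols = cols if training else None
        self._in_shape = x.shape
        return out.transpose(0, 2, 1).reshape(n, self.c_out, d, h, w)

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        n, f, d, h, w = dout.shape
        dmat = dout.reshape(n, f, d * h * w).transpose(0, 2, 1)  # (N, P, F)
        if need_param_grads:
            if self._cols is None:
                raise RuntimeError("backward called without a training forward pass")
            kdim = self._cols.shape[-1]
            dw = self._cols.reshape(-1, kdim).T @ dmat.reshape(-1, f)  # (C*k^3, F)
            self.weight.grad[...] = dw.T.reshape(self.weight.value.shape)
            self.bias.grad[...] = dmat.sum(axis=(0, 1))
        # dx = conv(dout, spatially flipped kernel with in/out channels swapped)
        w_rot = self.weight.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        cols = _im2col(dout, self.k)
        dx = cols @ np.ascontiguousarray(w_rot.reshape(self.c_in, -1).T)
        return dx.transpose(0, 2, 1).reshape(*self._in_shape)


class BatchNorm3d:
    """Per-channel batch normalization over (N, D, H, W); running stats at eval."""

    def __init__(self, c: int, name: str = "bn", momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c), kernel=False, name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(c), kernel=False, name=f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None
        self._eval_mode = False

    @property
    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    @staticmethod
    def _bc(v: np.ndarray) -> np.ndarray:
        return v.reshape(1, -1, 1, 1, 1)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3, 4))
            var = x.var(axis=(0, 2, 3, 4))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - self._bc(mean)) * self._bc(invstd)
            self._cache = (xhat, invstd)
            self._eval_mode = False
        else:
            invstd = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self._bc(self.running_mean)) * self._bc(invstd)
            self._cache = (None, invstd)
            self._eval_mode = True
        return self._bc(self.gamma.value) * xhat + self._bc(self.beta.value)

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        xhat, invstd = self._cache
        if self._eval_mode:
            # affine transform with frozen statistics
            if need_param_grads:
                self.gamma.grad[...] = (dout * xhat).sum(axis=(0, 2, 3, 4))
                self.beta.grad[...] = dout.sum(axis=(0, 2, 3, 4))
            return dout * self._bc(self.gamma.value * invstd)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        dgamma = (dout * xhat).sum(axis=(0, 2, 3, 4))
        dbeta = dout.sum(axis=(0, 2, 3, 4))
        if need_param_grads:
            self.gamma.grad[...] = dgamma
            self.beta.grad[...] = dbeta
        dx = self._bc(self.gamma.value * invstd) * (
            dout - self._bc(dbeta / m) - xhat * self._bc(dgamma / m)
        )
        return dx.astype(np.float32)


class ReLU:
    params: list[Parameter] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        return dout * self._mask


class MaxPool3d:
    """2x2x2 max pooling, stride 2 (axes must be even)."""

    params: list[Parameter] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        v = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        v = v.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, d // 2, h // 2, w // 2, 8
        )
        self._arg = v.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(v, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        flat = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=dout.dtype)
        np.put_along_axis(flat, self._arg[..., None], dout[..., None], axis=-1)
        flat = flat.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        return flat.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)


class Flatten:
    params: list[Parameter] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Dense:
    """Fully connected layer mapping the flattened final block to one output."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "fc"):
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.weight = Parameter(w, kernel=True, name=f"{name}.weight")
        self.bias = Parameter(np.zeros(n_out), kernel=False, name=f"{name}.bias")

    @property
    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dout: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        if need_param_grads:
            self.weight.grad[...] = self._x.T @ dout
            self.bias.grad[...] = dout.sum(axis=0)
        return dout @ self.weight.value.T
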