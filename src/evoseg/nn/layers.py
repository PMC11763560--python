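"""Channels-last (B, H, W, C) float32 layers with hand-written gradients.

Convolutions are evaluated as im2col + BLAS matmul, the standard trick for
fast CPU convolution in pure NumPy: the 3x3 neighborhood of every pixel is
gathered into a (B*H*W, 9*C) matrix through a sliding-window view and one
contiguous copy, so both the forward pass and the weight/input gradients
are single matrix products.  Upsampling is a learned 2x2 stride-2 transposed convolution,
which (having no overlap) reduces to one matmul and a reshape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv3x3",
    "Conv1x1",
    "ReLU",
    "MaxPool2",
    "UpConv2x2",
    "Dropout",
    "Adam",
]


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(B, H, W, C) -> (B, H, W, 9*C) of 3x3 neighborhoods, zero-padded.

    Gathered through a sliding-window view and one contiguous copy, which
    beats per-offset slice assignment on CPU.
    """
    b, h, w, c = x.shape
    xp = np.zeros((b, h + 2, w + 2, c), dtype=x.dtype)
    xp[:, 1 : h + 1, 1 : w + 1, :] = x
    v = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    cols = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))
    return cols.reshape(b, h, w, 9 * c)


def _col2im3(dcols: np.ndarray, c: int) -> np.ndarray:
    """Adjoint of :func:`_im2col3`: scatter-add neighborhoods back."""
    b, h, w, _ = dcols.shape
    d = dcols.reshape(b, h, w, 9, c)
    dxp = np.zeros((b, h + 2, w + 2, c), dtype=dcols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, di : di + h, dj : dj + w, :] += d[:, :, :, k, :]
            k += 1
    return dxp[:, 1 : h + 1, 1 : w + 1, :]


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero padding 1 ('same'), He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(2.0 / (9 * c_in))
        self.params["W"] = std * rng.standard_normal((9 * c_in, c_out), dtype=np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols = _im2col3(x)
        self._cols = cols if train else None
        y = cols @ self.params["W"] + self.params["b"]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols = self._cols
        flat_cols = cols.reshape(-1, cols.shape[-1])
        flat_dy = dy.reshape(-1, self.c_out)
        self.grads["W"] = flat_cols.T @ flat_dy
        self.grads["b"] = flat_dy.sum(axis=0)
        dcols = dy @ self.params["W"].T
        self._cols = None
        return _col2im3(dcols, self.c_in)


class Conv1x1(Layer):
    """1x1 convolution (per-pixel linear map), used for the output head."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(2.0 / c_in)
        self.params["W"] = std * rng.standard_normal((c_in, c_out), dtype=np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        flat_x = self._x.reshape(-1, self.c_in)
        flat_dy = dy.reshape(-1, self.c_out)
        self.grads["W"] = flat_x.T @ flat_dy
        self.grads["b"] = flat_dy.sum(axis=0)
        self._x = None
        return dy @ self.params["W"].T


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        self._mask = x > 0 if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; gradient routed to the first argmax."""

    def __init__(self) -> None:
        super().__init__()
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        xr = (
            x.reshape(b, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(b, h // 2, w // 2, c, 4)
        )
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        dxr = np.zeros((b, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = (
            dxr.reshape(b, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(b, h, w, c)
        )
        self._idx = None
        self._shape = None
        return dx


class UpConv2x2(Layer):
    """Learned 2x2 stride-2 transposed convolution (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(2.0 / c_in)
        self.params["W"] = std * rng.standard_normal((c_in, 4 * c_out), dtype=np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        b, h, w, _ = x.shape
        t = x @ self.params["W"]  # (b, h, w, 4*c_out)
        t = t.reshape(b, h, w, 2, 2, self.c_out)
        y = t.transpose(0, 1, 3, 2, 4, 5).reshape(b, 2 * h, 2 * w, self.c_out)
        return y + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h2, w2, _ = dy.shape
        h, w = h2 // 2, w2 // 2
        dt = (
            dy.reshape(b, h, 2, w, 2, self.c_out)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h, w, 4 * self.c_out)
        )
        flat_x = self._x.reshape(-1, self.c_in)
        flat_dt = dt.reshape(-1, 4 * self.c_out)
        self.grads["W"] = flat_x.T @ flat_dt
        self.grads["b"] = dy.reshape(-1, self.c_out).sum(axis=0)
        self._x = None
        return dt @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1.0 - self.beta2) * (g * g)
                p -= self.lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + self.eps)
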