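"""Minimal 1D neural-network engine (numpy, CPU).

Implements exactly the pieces the two-branch spectral classifier needs:
stride-1 "same" 1D convolution computed as cross-correlation (im2col +
BLAS matmul), non-overlapping max pooling, dense layers, inverted dropout,
sigmoid/binary-cross-entropy with logits, and Adam.  Forward and backward
passes are hand-derived; gradients and layer outputs are validated against
brute-force oracles in the test suite.

Array convention: trainable-layer activations are ``(length, batch,
channels)`` float32; the length-major layout keeps every convolution tap a
single contiguous BLAS matmul.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv1d",
    "maxpool1d",
    "ConvLayer",
    "MaxPool",
    "Dense",
    "Dropout",
    "Adam",
    "sigmoid",
    "bce_with_logits",
    "glorot_uniform",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient wrt the logits."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y) / z.size
    return float(loss), grad.astype(logits.dtype)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# functional ops (single sample, arbitrary channels) — the reference surface


def conv1d(
    x: np.ndarray,
    kernels: np.ndarray,
    bias: np.ndarray | float = 0.0,
    padding: str = "valid",
) -> np.ndarray:
    """ReLU(cross-correlation(x, kernels) + bias) for one sample.

    Parameters
    ----------
    x : (L,) or (L, C_in) array
    kernels : (C_out, C_in, K) array (or (K,) shorthand for 1→1 channels)
    bias : (C_out,) array or scalar
    padding : "valid" or "same" (zero padding, stride 1)
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    kernels = np.asarray(kernels, dtype=np.float64)
    if kernels.ndim == 1:
        kernels = kernels[None, None, :]
    c_out, c_in, k = kernels.shape
    if x.shape[1] != c_in:
        raise ValueError(f"input has {x.shape[1]} channels, kernels expect {c_in}")
    if x.shape[0] < k:
        raise ValueError(f"input length {x.shape[0]} shorter than kernel size {k}")
    if padding == "same":
        pl = (k - 1) // 2
        x = np.pad(x, ((pl, k - 1 - pl), (0, 0)))
    elif padding != "valid":
        raise ValueError("padding must be 'valid' or 'same'")
    cols = sliding_window_view(x, k, axis=0)          # (L_out, C_in, K)
    z = np.einsum("lck,ock->lo", cols, kernels) + np.asarray(bias)
    return np.maximum(z, 0.0)


def maxpool1d(x: np.ndarray, size: int, stride: int | None = None) -> np.ndarray:
    """Windowed maximum along the first axis; trailing remainder dropped."""
    if size < 1:
        raise ValueError("pool size must be >= 1")
    stride = size if stride is None else stride
    if stride < 1:
        raise ValueError("pool stride must be >= 1")
    x = np.asarray(x)
    if x.shape[0] < size:
        raise ValueError(f"input length {x.shape[0]} shorter than pool size {size}")
    starts = np.arange(0, x.shape[0] - size + 1, stride)
    return np.stack([x[s : s + size].max(axis=0) for s in starts])


# ---------------------------------------------------------------------------
# trainable layers (batched)


class ConvLayer:
    """Stride-1 'same' convolution + ReLU.

    Activations use the ``(length, batch, channels)`` layout: each of the K
    kernel taps then contributes one large contiguous BLAS matmul
    ``(L·B, C_in) @ (C_in, C_out)`` on a view of the zero-padded input — no
    im2col copy and no per-sample gemm splitting.  Weights are stored as
    ``(K, C_in, C_out)``; the equivalent ``(C_out, C_in, K)`` kernel tensor
    is exposed as ``kernels``.  Set ``skip_input_grad`` on the first layer
    of a network to avoid computing the unused gradient wrt the raw input.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.w = glorot_uniform(rng, (k, c_in, c_out), fan_in=c_in * k, fan_out=c_out * k)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.skip_input_grad = False
        self._xp: np.ndarray | None = None
        self._mask: np.ndarray | None = None

    @property
    def kernels(self) -> np.ndarray:
        return self.w.transpose(2, 1, 0)

    @kernels.setter
    def kernels(self, value: np.ndarray) -> None:
        self.w = np.ascontiguousarray(
            np.asarray(value, dtype=np.float32).transpose(2, 1, 0)
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        l, b, _ = x.shape
        pl = (self.k - 1) // 2
        xp = np.pad(x, ((pl, self.k - 1 - pl), (0, 0), (0, 0)))
        z = np.empty((l, b, self.c_out), dtype=self.w.dtype)
        z[:] = self.b
        z2 = z.reshape(l * b, self.c_out)
        tmp = np.empty_like(z2)
        for k in range(self.k):
            np.matmul(xp[k : k + l].reshape(l * b, self.c_in), self.w[k], out=tmp)
            z2 += tmp
        y = np.maximum(z, 0.0, out=z)
        if train:
            self._xp = xp
            self._mask = y > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        l, b, _ = dy.shape
        dz = np.multiply(dy, self._mask, dtype=dy.dtype)
        dz2 = dz.reshape(l * b, self.c_out)
        self.db = dz2.sum(axis=0)
        pl = (self.k - 1) // 2
        xp = self._xp
        for k in range(self.k):
            self.dw[k] = xp[k : k + l].reshape(l * b, self.c_in).T @ dz2
        dx = None
        if not self.skip_input_grad:
            dxp = np.zeros_like(xp)
            tmp = np.empty((l * b, self.c_in), dtype=dz.dtype)
            for k in range(self.k):
                np.matmul(dz2, self.w[k].T, out=tmp)
                dxp[k : k + l] += tmp.reshape(l, b, self.c_in)
            dx = dxp[pl : pl + l]
        self._xp = None
        self._mask = None
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class MaxPool:
    """Non-overlapping max pooling along axis 0 (size == stride).

    Activations are ``(length, batch, channels)``; a trailing remainder
    window is dropped.
    """

    def __init__(self, size: int = 2):
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.size = size
        self._mask2: np.ndarray | None = None
        self._idx: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        l = x.shape[0]
        s = self.size
        l2 = l // s
        if s == 2:  # fast path: boolean winner mask instead of argmax
            a = x[0 : l2 * 2 : 2]
            bb = x[1 : l2 * 2 : 2]
            y = np.maximum(a, bb)
            if train:
                self._mask2 = a >= bb
                self._in_len = l
            return y
        xr = x[: l2 * s].reshape(l2, s, *x.shape[1:])
        y = xr.max(axis=1)
        if train:
            self._idx = xr.argmax(axis=1)
            self._in_len = l
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        l2 = dy.shape[0]
        s = self.size
        dx = np.zeros((self._in_len, *dy.shape[1:]), dtype=dy.dtype)
        if s == 2:
            dx[0 : l2 * 2 : 2] = np.multiply(dy, self._mask2, dtype=dy.dtype)
            dx[1 : l2 * 2 : 2] = np.multiply(dy, ~self._mask2, dtype=dy.dtype)
            self._mask2 = None
            return dx
        dxr = np.zeros((l2, s, *dy.shape[1:]), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[:, None], dy[:, None], axis=1)
        dx[: l2 * s] = dxr.reshape(l2 * s, *dy.shape[1:])
        self._idx = None
        return dx

    def params(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu: bool = False):
        self.w = glorot_uniform(rng, (n_in, n_out), fan_in=n_in, fan_out=n_out)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.relu = relu
        self._x: np.ndarray | None = None
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = x @ self.w + self.b
        y = np.maximum(z, 0.0, out=z) if self.relu else z
        if train:
            self._x = x
            self._mask = y > 0 if self.relu else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = np.multiply(dy, self._mask, dtype=dy.dtype) if self.relu else dy
        self.dw = self._x.T @ dz
        self.db = dz.sum(axis=0)
        dx = dz @ self.w.T
        self._x = None
        self._mask = None
        return dx

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Dropout:
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        out = dy * self._mask
        self._mask = None
        return out

    def params(self):
        return []


class Adam:
    """Adam optimizer with the conventional defaults (β1 0.9, β2 0.999, ε 1e-7)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params_and_grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p, _ in params_and_grads]
            self._v = [np.zeros_like(p) for p, _ in params_and_grads]
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(params_and_grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
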