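"""Minimal 3D convolutional layer engine with analytic backward passes.

Tensors are ``float32`` arrays of layout ``(batch, channels, x, y, z)``.
Each layer caches what its backward pass needs; ``backward`` consumes the
gradient of the loss with respect to the layer output and returns the
gradient with respect to its input, accumulating parameter gradients on the
layer.  Only the pieces the segmentation blocks need are implemented:
3x3x3 "same" convolution (stride 1 or 2), batch normalization, ReLU,
sigmoid, 2x nearest-neighbour upsampling, channel concatenation, and Adam.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "Sigmoid",
    "NearestUpsample3d",
    "Adam",
]

_OFFSETS = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]


class Layer:
    params: List[np.ndarray]
    grads: List[np.ndarray]

    def __init__(self):
        self.params = []
        self.grads = []
        self.training = True

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def state(self) -> List[np.ndarray]:
        """Arrays to persist in a checkpoint (parameters by default)."""
        return self.params

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0


class Conv3d(Layer):
    """3x3x3 convolution with symmetric 1-voxel zero padding.

    ``stride=2`` halves every spatial dimension (inputs must have even
    extents).  ``bias`` is off by default because the convolutions of the
    segmentation blocks are immediately batch-normalized.
    """

    def __init__(self, cin: int, cout: int, stride: int = 1, bias: bool = False,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        rng = rng or np.random.default_rng(0)
        fan_in = cin * 27
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, 3, 3, 3)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32) if bias else None
        self.stride = stride
        self.cin, self.cout = cin, cout
        self.params = [self.w] + ([self.b] if bias else [])
        self.grads = [np.zeros_like(p) for p in self.params]
        self._xp = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, X, Y, Z = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        s = self.stride
        if s == 2 and any(d % 2 for d in (X, Y, Z)):
            raise ValueError(f"stride-2 convolution needs even extents, got {(X, Y, Z)}")
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        Xo, Yo, Zo = X // s, Y // s, Z // s
        y = np.zeros((n, self.cout, Xo * Yo * Zo), dtype=np.float32)
        for i, j, k in _OFFSETS:
            xs = xp[:, :, i:i + X:s, j:j + Y:s, k:k + Z:s]
            y += self.w[:, :, i, j, k] @ xs.reshape(n, self.cin, -1)
        y = y.reshape(n, self.cout, Xo, Yo, Zo)
        if self.b is not None:
            y += self.b[None, :, None, None, None]
        self._xp = xp
        self._in_shape = (X, Y, Z)
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        n = dy.shape[0]
        X, Y, Z = self._in_shape
        s = self.stride
        dyf = dy.reshape(n, self.cout, -1)
        dyt = np.ascontiguousarray(dyf.transpose(1, 0, 2)).reshape(self.cout, -1)
        dw = self.grads[0]
        dxp = np.zeros_like(self._xp) if need_dx else None
        nv = dyt.shape[1]
        for i, j, k in _OFFSETS:
            xs = self._xp[:, :, i:i + X:s, j:j + Y:s, k:k + Z:s]
            xst = np.ascontiguousarray(
                xs.reshape(n, self.cin, -1).transpose(1, 0, 2)
            ).reshape(self.cin, nv)
            dw[:, :, i, j, k] += dyt @ xst.T
            if need_dx:
                dxs = (self.w[:, :, i, j, k].T @ dyf).reshape(xs.shape)
                dxp[:, :, i:i + X:s, j:j + Y:s, k:k + Z:s] += dxs
        if self.b is not None:
            self.grads[1] += dyf.sum(axis=(0, 2))
        self._xp = None
        if not need_dx:
            return None
        return dxp[:, :, 1:-1, 1:-1, 1:-1]


class BatchNorm3d(Layer):
    """Per-channel batch normalization with affine scale and shift."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def state(self):
        return self.params + [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean *= 1.0 - m
            self.running_mean += m * mean
            self.running_var *= 1.0 - m
            self.running_var += m * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * invstd[None, :, None, None, None]
        if self.training:
            self._xhat = xhat
            self._invstd = invstd
        return self.gamma[None, :, None, None, None] * xhat + self.beta[None, :, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        xhat, invstd = self._xhat, self._invstd
        m = float(dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4])
        self.grads[0] += np.sum(dy * xhat, axis=axes)
        self.grads[1] += np.sum(dy, axis=axes)
        g = self.gamma[None, :, None, None, None]
        dy_sum = np.sum(dy, axis=axes)[None, :, None, None, None]
        dyx_sum = np.sum(dy * xhat, axis=axes)[None, :, None, None, None]
        dx = (g * invstd[None, :, None, None, None] / m) * (
            m * dy - dy_sum - xhat * dyx_sum
        )
        self._xhat = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class Sigmoid(Layer):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-x))
        self._y = y
        return y

    def backward(self, dy):
        dx = dy * self._y * (1.0 - self._y)
        self._y = None
        return dx


class NearestUpsample3d(Layer):
    """2x nearest-neighbour upsampling along every spatial axis."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dy):
        n, c, X, Y, Z = dy.shape
        return dy.reshape(n, c, X // 2, 2, Y // 2, 2, Z // 2, 2).sum(axis=(3, 5, 7))


class Adam:
    """Adam optimizer over an explicit (params, grads) list."""

    def __init__(self, layers: Sequence[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for li, l in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(l.params, l.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= b1
                m += (1.0 - b1) * g
                v *= b2
                v += (1.0 - b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
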