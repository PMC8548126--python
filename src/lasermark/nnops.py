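"""Minimal CPU neural-network primitives with explicit backpropagation.

Layout is channels-last ``(N, H, W, C)`` float32 throughout.  Convolutions
are stride-1 "same" correlations computed as a sum of shifted GEMMs, which
keeps the inner loop inside BLAS without materializing an im2col buffer.
Each layer caches what its backward pass needs and owns its parameter and
gradient arrays; the optimizer walks ``parameters()``.
"""

from __future__ import annotations

import numpy as np


def _shift_corr(x: np.ndarray, weights: np.ndarray, pad: tuple[int, int, int, int]) -> np.ndarray:
    """Stride-1 correlation of ``x`` (N,H,W,C) with ``weights`` (kh,kw,C,F)."""
    kh, kw = weights.shape[:2]
    pt, pb, pl, pr = pad
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    n, hp, wp, _ = xp.shape
    h_out = hp - kh + 1
    w_out = wp - kw + 1
    out = np.zeros((n, h_out, w_out, weights.shape[3]), dtype=np.float32)
    tmp = np.empty_like(out)
    for i in range(kh):
        for j in range(kw):
            np.matmul(xp[:, i : i + h_out, j : j + w_out, :], weights[i, j], out=tmp)
            out += tmp
    return out


class Conv2D:
    """Same-size stride-1 convolution.  Odd kernels pad symmetrically; even
    kernels pad one extra pixel on the bottom/right."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, k: int):
        scale = np.sqrt(2.0 / (k * k * cin))  # He initialization for ReLU stacks
        self.weight = (rng.standard_normal((k, k, cin, cout)) * scale).astype(np.float32)
        self.bias = np.zeros(cout, dtype=np.float32)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self.k = k
        pt = (k - 1) // 2
        self.pad = (pt, k - 1 - pt, pt, k - 1 - pt)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return _shift_corr(x, self.weight, self.pad) + self.bias

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        k = self.k
        pt, pb, pl, pr = self.pad
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        h_out, w_out = dy.shape[1:3]
        dy2 = np.ascontiguousarray(dy).reshape(-1, dy.shape[-1])
        cin = xp.shape[-1]
        for i in range(k):
            for j in range(k):
                # contiguous copy + GEMM beats tensordot's internal transpose
                patch = np.ascontiguousarray(
                    xp[:, i : i + h_out, j : j + w_out, :]
                ).reshape(-1, cin)
                self.grad_weight[i, j] = patch.T @ dy2
        self.grad_bias[...] = dy.sum(axis=(0, 1, 2))
        # dx: full correlation of dy with the flipped, transposed kernel
        w_flip = self.weight[::-1, ::-1].transpose(0, 1, 3, 2)
        back_pad = (k - 1 - pt, k - 1 - pb, k - 1 - pl, k - 1 - pr)
        dx = _shift_corr(dy, np.ascontiguousarray(w_flip), back_pad)
        self._x = None
        return dx

    def parameters(self):
        yield "weight", self.weight, self.grad_weight
        yield "bias", self.bias, self.grad_bias


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    def parameters(self):
        return iter(())


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx

    def parameters(self):
        return iter(())


class MaxPool2x2:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, 4, c)
        idx = xr.argmax(axis=3)
        out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        self._idx = None
        return np.ascontiguousarray(dx).reshape(n, h, w, c)

    def parameters(self):
        return iter(())


class UpsampleNearest2x:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))

    def parameters(self):
        return iter(())


class TransposedUpsample2x:
    """2x upsampling as a stride-2 transposed convolution with a 2x2 kernel."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int):
        scale = np.sqrt(2.0 / cin)
        self.weight = (rng.standard_normal((2, 2, cin, cout)) * scale).astype(np.float32)
        self.bias = np.zeros(cout, dtype=np.float32)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        n, h, w, c = x.shape
        out = np.empty((n, 2 * h, 2 * w, self.weight.shape[3]), dtype=np.float32)
        for i in range(2):
            for j in range(2):
                out[:, i::2, j::2, :] = x @ self.weight[i, j]
        return out + self.bias

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        dx = np.zeros_like(x)
        for i in range(2):
            for j in range(2):
                sub = dy[:, i::2, j::2, :]
                self.grad_weight[i, j] = np.tensordot(x, sub, axes=([0, 1, 2], [0, 1, 2]))
                dx += sub @ self.weight[i, j].T
        self.grad_bias[...] = dy.sum(axis=(0, 1, 2))
        self._x = None
        return dx

    def parameters(self):
        yield "weight", self.weight, self.grad_weight
        yield "bias", self.bias, self.grad_bias


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the trailing (channel) axis."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
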