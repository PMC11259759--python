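"""Minimal numpy neural-network layers for the polyreactivity classifier.

Only what the architecture needs: 3x3 same-padding convolutions (bias-free,
so all-zero padding bands stay exactly zero through the column), max pooling,
a masked global average pool whose denominator counts only rows carrying
sequence content (this makes predictions exactly invariant to appending
empty var slots), dense layers, inverted dropout, and Adam.

Everything is float32 and deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Conv2DSame:
    """k x k convolution without bias, 'same'-style padding of k//2.

    A stride of (sh, sw) fuses the block's downsampling into the convolution
    itself (output height ceil(H / sh)); bias-free means all-zero input
    regions map to all-zero outputs, which the masked global pool relies on.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: tuple[int, int] = (1, 1)):
        fan_in = kernel * kernel * c_in
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(kernel, kernel, c_in, c_out)).astype(F32)
        self.dW = np.zeros_like(self.W)
        self.k = kernel
        self.stride = stride
        self._xp = None

    def params(self):
        return [self.W]

    def grads(self):
        return [self.dW]

    @staticmethod
    def out_size(n: int, stride: int) -> int:
        return -(-n // stride)  # ceil

    def _patch(self, xp, di, dj, Ho, Wo):
        sh, sw = self.stride
        return xp[:, di : di + sh * (Ho - 1) + 1 : sh,
                  dj : dj + sw * (Wo - 1) + 1 : sw, :]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        sh, sw = self.stride
        Ho, Wo = self.out_size(H, sh), self.out_size(W, sw)
        c_out = self.W.shape[-1]
        y = np.zeros((B * Ho * Wo, c_out), dtype=F32)
        for di in range(self.k):
            for dj in range(self.k):
                patch = self._patch(xp, di, dj, Ho, Wo).reshape(-1, C)
                y += patch @ self.W[di, dj]
        return y.reshape(B, Ho, Wo, c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        B, Hp, Wp, C = xp.shape
        Ho, Wo = dy.shape[1], dy.shape[2]
        c_out = self.W.shape[-1]
        dy_flat = dy.reshape(-1, c_out)
        dxp = np.zeros_like(xp)
        sh, sw = self.stride
        for di in range(self.k):
            for dj in range(self.k):
                patch = self._patch(xp, di, dj, Ho, Wo).reshape(-1, C)
                self.dW[di, dj] = patch.T @ dy_flat
                self._patch(dxp, di, dj, Ho, Wo)[...] += (
                    dy_flat @ self.W[di, dj].T
                ).reshape(B, Ho, Wo, C)
        p = self.k // 2
        H, W = Hp - 2 * p, Wp - 2 * p
        return dxp[:, p : p + H, p : p + W, :]

    @staticmethod
    def downsample_mask(mask: np.ndarray, sh: int, k: int = 3) -> np.ndarray:
        """Row-activity mask after a strided 'same' convolution: an output
        row is active when any input row in its receptive field is."""
        B, H = mask.shape
        p = k // 2
        mp = np.zeros((B, H + 2 * p), dtype=bool)
        mp[:, p : p + H] = mask
        Ho = Conv2DSame.out_size(H, sh)
        out = np.zeros((B, Ho), dtype=bool)
        for d in range(k):
            sl = mp[:, d : d + sh * (Ho - 1) + 1 : sh]
            out |= sl
        return out


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, F32(0.0))


class MaxPool2D:
    """Non-overlapping max pool, floor mode (trailing remainder dropped)."""

    def __init__(self, pool: tuple[int, int]):
        self.ph, self.pw = pool
        self._cache = None

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        Ho, Wo = H // self.ph, W // self.pw
        xc = x[:, : Ho * self.ph, : Wo * self.pw, :]
        v = xc.reshape(B, Ho, self.ph, Wo, self.pw, C)
        y = v.max(axis=(2, 4))
        self._cache = (v, y, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        v, y, xshape = self._cache
        mask = v == y[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dv = mask * (dy[:, :, None, :, None, :] / counts)
        B, Ho, ph, Wo, pw, C = v.shape
        dx = np.zeros(xshape, dtype=F32)
        dx[:, : Ho * ph, : Wo * pw, :] = dv.reshape(B, Ho * ph, Wo * pw, C)
        return dx

    @staticmethod
    def pool_mask(mask: np.ndarray, ph: int) -> np.ndarray:
        """Downsample a (B, H) row-activity mask by factor ph (max, floor)."""
        B, H = mask.shape
        Ho = H // ph
        return mask[:, : Ho * ph].reshape(B, Ho, ph).any(axis=2)


class MaskedGlobalAvgPool:
    """Average over spatial positions, normalising by active rows only.

    The numerator sums every position (inactive rows contribute exactly zero
    for bias-free columns); the denominator is (#active rows x width), so
    appending all-zero slots leaves the output bit-identical.
    """

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, row_mask: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        n_active = np.maximum(row_mask.sum(axis=1), 1).astype(F32)  # (B,)
        denom = (n_active * W)[:, None]
        y = x.sum(axis=(1, 2)) / denom
        self._cache = (x.shape, denom)
        return y.astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (B, H, W, C), denom = self._cache
        return (dy / denom)[:, None, None, :] * np.ones((B, H, W, C), dtype=F32)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            self.W = np.zeros((n_in, n_out), dtype=F32)
        else:
            self.W = rng.normal(0.0, np.sqrt(2.0 / n_in),
                                size=(n_in, n_out)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Adam:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p -= F32(lr) * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(probs: np.ndarray, y: np.ndarray,
             sample_weight: np.ndarray | None = None) -> float:
    p = np.clip(probs, 1e-7, 1.0 - 1e-7)
    ll = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    if sample_weight is not None:
        ll = ll * sample_weight
    return float(ll.mean())
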