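"""Minimal 3-D convolutional encoder-decoder with explicit backpropagation.

A deliberately small, dependency-free network used as the SPEND denoising
backbone: two resolution levels (3x3x3 convolutions + ReLU, average-pool
down, nearest-neighbour up, skip concatenation) with a global residual
connection, trained with Adam on a mean-squared-error objective. All
tensors are float32 NCDHW with a leading batch dimension; convolutions use
zero padding so shapes are preserved.

The implementation favours clarity over speed: convolutions are im2col GEMM
in the forward pass and 27 shifted slice-adds in the backward pass. It is
fast enough to train on ~64^3 volumes in minutes on one CPU core.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ConvNet3d", "Adam", "mse_loss"]

_K = 3  # kernel edge; fixed 3x3x3


def _he_init(rng: np.random.Generator, c_in: int, c_out: int) -> np.ndarray:
    fan_in = c_in * _K**3
    return (rng.standard_normal((c_in * _K**3, c_out)) * np.sqrt(2.0 / fan_in)).astype(
        np.float32
    )


class _Conv3d:
    """Same-padding 3x3x3 convolution, im2col forward / slice-add backward."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int):
        self.c_in, self.c_out = c_in, c_out
        self.w = _he_init(rng, c_in, c_out)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, d, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (_K, _K, _K), axis=(2, 3, 4))
        # (b, c, d, h, w, 3,3,3) -> (b*d*h*w, c*27)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            b * d * h * w, c * _K**3
        )
        out = cols @ self.w + self.b
        if train:
            self._cols, self._shape = cols, (b, c, d, h, w)
        return np.ascontiguousarray(
            out.reshape(b, d, h, w, self.c_out).transpose(0, 4, 1, 2, 3)
        )

    def backward(self, gout: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._shape is not None
        b, c, d, h, w = self._shape
        g2 = np.ascontiguousarray(gout.transpose(0, 2, 3, 4, 1)).reshape(-1, self.c_out)
        self.gw = self._cols.T @ g2
        self.gb = g2.sum(axis=0)
        gcols = (g2 @ self.w.T).reshape(b, d, h, w, c, _K, _K, _K)
        gxp = np.zeros((b, c, d + 2, h + 2, w + 2), dtype=gout.dtype)
        gcols = gcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)  # (b, c, d, h, w, 3,3,3)
        for dz in range(_K):
            for dy in range(_K):
                for dx in range(_K):
                    gxp[:, :, dz : dz + d, dy : dy + h, dx : dx + w] += gcols[
                        ..., dz, dy, dx
                    ]
        self._cols = None
        return gxp[:, :, 1:-1, 1:-1, 1:-1]

    @property
    def params(self):
        return [("w", self), ("b", self)]


def _relu_forward(x):
    mask = x > 0
    return x * mask, mask


def _avgpool2(x):
    b, c, d, h, w = x.shape
    return x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))


def _avgpool2_backward(g, shape):
    g = g[:, :, :, None, :, None, :, None] / 8.0
    g = np.broadcast_to(
        g, (g.shape[0], g.shape[1], g.shape[2], 2, g.shape[4], 2, g.shape[6], 2)
    )
    return g.reshape(shape)


def _upsample2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)


def _upsample2_backward(g):
    b, c, d, h, w = g.shape
    return g.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


class ConvNet3d:
    """Residual denoising network.

    depth=1: conv(1->c) - conv(c->c) - conv(c->1), ReLU between.
    depth=2: adds an average-pooled bottleneck at half resolution with
    channel doubling and a skip concatenation before the decoder.
    Input volumes must have even edge lengths when depth=2.
    """

    def __init__(self, base_channels: int = 8, depth: int = 2, seed: int = 0):
        if depth not in (1, 2):
            raise ValueError("depth must be 1 or 2")
        rng = np.random.default_rng(seed)
        c = int(base_channels)
        self.depth = depth
        self.base_channels = c
        self.enc1 = _Conv3d(rng, 1, c)
        self.enc2 = _Conv3d(rng, c, c)
        if depth == 2:
            self.bot1 = _Conv3d(rng, c, 2 * c)
            self.bot2 = _Conv3d(rng, 2 * c, 2 * c)
            self.dec1 = _Conv3d(rng, 3 * c, c)
        else:
            self.dec1 = _Conv3d(rng, c, c)
        self.out = _Conv3d(rng, c, 1)
        self._cache: dict = {}

    def convs(self) -> list[_Conv3d]:
        layers = [self.enc1, self.enc2]
        if self.depth == 2:
            layers += [self.bot1, self.bot2]
        layers += [self.dec1, self.out]
        return layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x)
        if x.dtype not in (np.float32, np.float64):
            x = x.astype(np.float32)
        if self.depth == 2 and any(s % 2 for s in x.shape[2:]):
            raise ValueError("depth-2 network needs even volume edge lengths")
        cache = {}
        e1, cache["m1"] = _relu_forward(self.enc1.forward(x, train))
        e2, cache["m2"] = _relu_forward(self.enc2.forward(e1, train))
        if self.depth == 2:
            p = _avgpool2(e2)
            b1, cache["mb1"] = _relu_forward(self.bot1.forward(p, train))
            b2, cache["mb2"] = _relu_forward(self.bot2.forward(b1, train))
            u = _upsample2(b2)
            cat = np.concatenate([e2, u], axis=1)
            cache["e2_shape"] = e2.shape
            d1, cache["md"] = _relu_forward(self.dec1.forward(cat, train))
        else:
            d1, cache["md"] = _relu_forward(self.dec1.forward(e2, train))
        y = self.out.forward(d1, train) + x  # global residual
        if train:
            self._cache = cache
        return y

    def backward(self, gy: np.ndarray) -> None:
        cache = self._cache
        gd1 = self.out.backward(gy.astype(np.float32, copy=False))
        gd1 *= cache["md"]
        if self.depth == 2:
            gcat = self.dec1.backward(gd1)
            c = cache["e2_shape"][1]
            ge2 = gcat[:, :c]
            gu = gcat[:, c:]
            gb2 = _upsample2_backward(gu) * cache["mb2"]
            gb1 = self.bot2.backward(gb2) * cache["mb1"]
            gp = self.bot1.backward(gb1)
            ge2 = ge2 + _avgpool2_backward(gp, cache["e2_shape"])
        else:
            ge2 = self.dec1.backward(gd1)
        ge2 = ge2 * cache["m2"]
        ge1 = self.enc2.backward(ge2) * cache["m1"]
        self.enc1.backward(ge1)
        self._cache = {}

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, conv in enumerate(self.convs()):
            state[f"conv{i}_w"] = conv.w
            state[f"conv{i}_b"] = conv.b
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, conv in enumerate(self.convs()):
            conv.w = np.asarray(state[f"conv{i}_w"], dtype=np.float32)
            conv.b = np.asarray(state[f"conv{i}_b"], dtype=np.float32)


class Adam:
    """Adam optimizer over a ConvNet3d's convolution parameters."""

    def __init__(self, net: ConvNet3d, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            (np.zeros_like(c.w), np.zeros_like(c.b)) for c in net.convs()
        ]
        self.v = [
            (np.zeros_like(c.w), np.zeros_like(c.b)) for c in net.convs()
        ]

    def step(self) -> None:
        self.t += 1
        bias1 = 1 - self.b1**self.t
        bias2 = 1 - self.b2**self.t
        for i, conv in enumerate(self.net.convs()):
            for j, (param, grad) in enumerate(((conv.w, conv.gw), (conv.b, conv.gb))):
                m = self.m[i][j]
                v = self.v[i][j]
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad**2
                param -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. `pred`."""
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff
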