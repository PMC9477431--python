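"""Neural-network layers on top of :mod:`e2sgan.autodiff`.

Implements the building blocks the translation networks use: 2-D convolution
with runtime weight scaling (equalized learning rate), pixel-wise feature
normalization, nearest-neighbour upsampling, and a stock Adam optimizer.
"""

from __future__ import annotations

import math

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = np.array(s, dtype=np.float64)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) via im2col + matmul."""
    if padding:
        x = ad.pad2d(x, padding)
    n, c, h, w = x.shape
    o, ci, k, _ = weight.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight {ci}")
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    cols = ad.unfold(x, k, stride)                 # (n, c*k*k, oh*ow)
    wm = ad.reshape(weight, (o, c * k * k))
    out = ad.reshape(wm @ cols, (n, o, oh, ow))
    if bias is not None:
        out = out + ad.reshape(bias, (1, o, 1, 1))
    return out


class EqualizedConv2d(Module):
    """Convolution with He-constant runtime weight scaling.

    Weights are stored as draws from N(0, 1) and multiplied by
    sqrt(2 / fan_in) at every forward pass, so the effective learning rate is
    equalized across layers regardless of fan-in.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 gain: float = math.sqrt(2.0)):
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.standard_normal((out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch))
        self.stride = stride
        self.padding = padding
        # gain sqrt(2) is the He constant for leaky-rectified layers; the
        # generator's Tanh head uses gain 1 to start unsaturated
        self.scale = gain / math.sqrt(in_ch * kernel * kernel)

    def __call__(self, x: Tensor) -> Tensor:
        w = self.weight * self.scale
        return conv2d(x, w, self.bias, stride=self.stride, padding=self.padding)


def pixel_norm(x: Tensor, eps: float = 1e-8) -> Tensor:
    """Normalize the channel vector at each spatial position to unit RMS."""
    ms = ad.tmean(x * x, axis=1, keepdims=True)
    return x * ad.pow_const(ms + eps, -0.5)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    n, c, h, w = x.shape
    x = ad.reshape(x, (n, c, h, 1, w, 1))
    x = ad.broadcast_to(x, (n, c, h, 2, w, 2))
    return ad.reshape(x, (n, c, 2 * h, 2 * w))


class Adam:
    """Adam over a parameter list; state lives outside the autodiff graph."""

    def __init__(self, params: list[Parameter], lr: float, beta1: float = 0.0,
                 beta2: float = 0.99, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads: list[Tensor]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * gd
            self.v[i] = b2 * self.v[i] + (1 - b2) * gd * gd
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
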