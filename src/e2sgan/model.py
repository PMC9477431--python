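"""Generator and critic networks for spectral-pair translation.

The generator is a convolutional encoder-decoder with a two-residual-block
bottleneck: two stride-2 downsampling convolutions (2 -> 32 -> 64 channels at
the default size), two nearest-neighbour-upsample + same-convolution stages,
and a 7x7 output head applied after padding the 128-wide feature map to a
spatial side of 134, ending in Tanh. Every hidden layer uses equalized
learning-rate scaling, leaky rectification and pixel-wise normalization.

The critic is a patch-based fully-convolutional network: five convolutions
map the (scalp, depth, attention) channel stack of a 128x128 pair down to a
14x14 grid of patch scores. Two auxiliary heads extend it:

* correlative spectral attention (CSA) — a mutual attention map between the
  scalp and depth magnitude channels, concatenated to the critic input as an
  extra channel;
* weighted patch prediction (WPP) — a learnable weighting of the flattened
  patch scores plus a leaky-rectified global mean term, reducing the patch
  grid to the scalar critic output.

All spatial sizes are derived from the configured input side, so a reduced
32x32 configuration runs the identical architecture at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclass
class ModelConfig:
    size: int = 128          # spatial side of the square spectral tensors
    gen_base: int = 32       # first encoder width; Table-faithful default
    disc_base: int = 16
    lrelu_slope: float = 0.2
    pixel_norm_eps: float = 1e-8
    head_pad: int = 3        # 128 -> 134 before the 7x7 output head
    use_csa: bool = True

    def __post_init__(self):
        if self.size % 8 != 0 or self.size < 16:
            raise ValueError("size must be a multiple of 8, at least 16")

    @property
    def patch_side(self) -> int:
        """Side k of the critic's patch grid (14 for 128-wide inputs)."""
        return self.size // 8 - 2

    @property
    def padded_side(self) -> int:
        """Spatial side after the generator's pre-head padding (134)."""
        return self.size + 2 * self.head_pad


class ResBlock(nn.Module):
    """Pre-activation residual block: two 3x3 same-convolutions."""

    def __init__(self, ch: int, cfg: ModelConfig, rng):
        self.c1 = nn.EqualizedConv2d(ch, ch, 3, padding=1, rng=rng)
        self.c2 = nn.EqualizedConv2d(ch, ch, 3, padding=1, rng=rng)
        self.cfg = cfg

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        h = self.c1(nn.pixel_norm(ad.leaky_relu(x, cfg.lrelu_slope),
                                  cfg.pixel_norm_eps))
        h = self.c2(nn.pixel_norm(ad.leaky_relu(h, cfg.lrelu_slope),
                                  cfg.pixel_norm_eps))
        return x + h


class Generator(nn.Module):
    """Deterministic spectral-to-spectral map; no noise input."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        cfg = cfg or ModelConfig()
        rng = np.random.default_rng(seed)
        b = cfg.gen_base
        self.cfg = cfg
        self.enc1 = nn.EqualizedConv2d(2, b, 4, stride=2, padding=1, rng=rng)
        self.enc2 = nn.EqualizedConv2d(b, 2 * b, 4, stride=2, padding=1, rng=rng)
        self.res = [ResBlock(2 * b, cfg, rng), ResBlock(2 * b, cfg, rng)]
        self.dec1 = nn.EqualizedConv2d(2 * b, b, 3, padding=1, rng=rng)
        self.dec2 = nn.EqualizedConv2d(b, max(b // 2, 4), 3, padding=1, rng=rng)
        self.head = nn.EqualizedConv2d(max(b // 2, 4), 2, 7, padding=0, rng=rng,
                                       gain=1.0)
        self.last_padded_side: int | None = None

    def _act(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        return nn.pixel_norm(ad.leaky_relu(x, cfg.lrelu_slope),
                             cfg.pixel_norm_eps)

    def __call__(self, e) -> Tensor:
        x = e if isinstance(e, Tensor) else Tensor(np.asarray(e, dtype=np.float64))
        squeeze = x.ndim == 3
        if squeeze:
            x = ad.reshape(x, (1,) + x.shape)
        if x.ndim != 4 or x.shape[1] != 2 or x.shape[2] != self.cfg.size \
                or x.shape[3] != self.cfg.size:
            raise ValueError(
                f"expected input (N, 2, {self.cfg.size}, {self.cfg.size}), "
                f"got {x.shape}")
        h = self._act(self.enc1(x))
        h = self._act(self.enc2(h))
        for block in self.res:
            h = block(h)
        h = self._act(self.dec1(nn.upsample2x(h)))
        h = self._act(self.dec2(nn.upsample2x(h)))
        h = ad.pad2d(h, self.cfg.head_pad)
        self.last_padded_side = h.shape[-1]
        out = ad.tanh(self.head(h))
        if squeeze:
            out = ad.reshape(out, out.shape[1:])
        return out


class CSA(nn.Module):
    """Correlative spectral attention between magnitude channels.

    Learned affine maps A1, A2 project the scalp and depth magnitude grids;
    the scaled product of the projections is row-softmaxed into a
    row-stochastic m x m attention matrix alpha, and the output is
    alpha @ E_mag — the scalp magnitude re-expressed through the learned
    scalp/depth frequency correlation.
    """

    def __init__(self, n: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        s = 1.0 / math.sqrt(n)
        self.n = n
        self.w1 = nn.Parameter(rng.standard_normal((n, n)) * s)
        self.b1 = nn.Parameter(np.zeros(n))
        self.w2 = nn.Parameter(rng.standard_normal((n, n)) * s)
        self.b2 = nn.Parameter(np.zeros(n))

    def attention(self, e_mag: Tensor, s_mag: Tensor) -> Tensor:
        a1 = (e_mag @ self.w1) + self.b1
        a2 = (s_mag @ self.w2) + self.b2
        scores = (a1 @ ad.swapaxes(a2, -1, -2)) * (1.0 / math.sqrt(self.n))
        return ad.softmax(scores, axis=-1)

    def __call__(self, e_mag: Tensor, s_mag: Tensor) -> Tensor:
        return self.attention(e_mag, s_mag) @ e_mag


class WPP(nn.Module):
    """Weighted patch prediction head.

    Flattens the k x k patch-score grid, prepends the leaky-rectified global
    mean, and contracts with k^2 + 1 learnable weights beta to the scalar
    critic output. Initialized to the uniform average so the untrained head
    reproduces plain patch-mean scoring.
    """

    def __init__(self, k: int, lrelu_slope: float = 0.2):
        self.k = k
        self.lrelu_slope = lrelu_slope
        self.beta = nn.Parameter(np.full(k * k + 1, 1.0 / (k * k + 1)))

    def __call__(self, patch_grid: Tensor) -> Tensor:
        n = patch_grid.shape[0]
        k2 = self.k * self.k
        p = ad.reshape(patch_grid, (n, k2))
        p_global = ad.leaky_relu(ad.tmean(p, axis=1, keepdims=True),
                                 self.lrelu_slope)
        q = ad.concat([p_global, p], axis=1)
        y = q @ ad.reshape(self.beta, (k2 + 1, 1))
        return ad.reshape(y, (n,))


class Discriminator(nn.Module):
    """Patch critic over (scalp, depth, attention) channel stacks.

    The trunk always has five input channels; when CSA is disabled the
    attention channel is fed as zeros, keeping one architecture across both
    training phases. No final nonlinearity (Wasserstein critic).
    """

    IN_CHANNELS = 5

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        cfg = cfg or ModelConfig()
        rng = np.random.default_rng(seed)
        b = cfg.disc_base
        self.cfg = cfg
        self.convs = [
            nn.EqualizedConv2d(self.IN_CHANNELS, b, 4, stride=2, padding=1, rng=rng),
            nn.EqualizedConv2d(b, 2 * b, 4, stride=2, padding=1, rng=rng),
            nn.EqualizedConv2d(2 * b, 4 * b, 4, stride=2, padding=1, rng=rng),
            nn.EqualizedConv2d(4 * b, 8 * b, 4, stride=1, padding=1, rng=rng),
            nn.EqualizedConv2d(8 * b, 1, 4, stride=1, padding=1, rng=rng),
        ]
        self.csa = CSA(cfg.size, seed=seed + 1)
        self.wpp = WPP(cfg.patch_side, cfg.lrelu_slope)

    def trunk(self, x5: Tensor) -> Tensor:
        h = x5
        for conv in self.convs[:-1]:
            h = ad.leaky_relu(conv(h), self.cfg.lrelu_slope)
        return self.convs[-1](h)

    def critic(self, pair: Tensor, use_csa: bool = True) -> Tensor:
        """Scalar critic score from a (N, 4, H, W) scalp+depth channel stack.

        The CSA channel is computed from the two magnitude channels of the
        stack itself, so input gradients flow through the attention path.
        """
        n, c, h, w = pair.shape
        if c != 4 or h != self.cfg.size or w != self.cfg.size:
            raise ValueError(f"expected (N, 4, {self.cfg.size}, {self.cfg.size}), "
                             f"got {pair.shape}")
        if use_csa:
            e_mag = ad.reshape(ad.narrow(pair, 1, 0, 1), (n, h, w))
            s_mag = ad.reshape(ad.narrow(pair, 1, 2, 1), (n, h, w))
            csa_ch = ad.reshape(self.csa(e_mag, s_mag), (n, 1, h, w))
        else:
            csa_ch = Tensor(np.zeros((n, 1, h, w)))
        x5 = ad.concat([pair, csa_ch], axis=1)
        return self.wpp(self.trunk(x5))

    def __call__(self, e, s, use_csa: bool = True) -> Tensor:
        e = e if isinstance(e, Tensor) else Tensor(np.asarray(e, dtype=np.float64))
        s = s if isinstance(s, Tensor) else Tensor(np.asarray(s, dtype=np.float64))
        if e.ndim == 3:
            e = ad.reshape(e, (1,) + e.shape)
        if s.ndim == 3:
            s = ad.reshape(s, (1,) + s.shape)
        if e.shape != s.shape:
            raise ValueError("scalp and depth stacks must share a shape")
        pair = ad.concat([e, s], axis=1)
        return self.critic(pair, use_csa=use_csa)


# ---------------------------------------------------------------------------
# functional wrappers operating on plain arrays
# ---------------------------------------------------------------------------

def generator_forward(gen: Generator, e: np.ndarray) -> np.ndarray:
    return gen(np.asarray(e, dtype=np.float64)).data


def csa_forward(e_mag: np.ndarray, s_mag: np.ndarray, csa: CSA) -> np.ndarray:
    e_mag = np.asarray(e_mag, dtype=np.float64)
    s_mag = np.asarray(s_mag, dtype=np.float64)
    if e_mag.shape != s_mag.shape:
        raise ValueError("magnitude grids must share a shape")
    squeeze = e_mag.ndim == 2
    if squeeze:
        e_mag, s_mag = e_mag[None], s_mag[None]
    out = csa(Tensor(e_mag), Tensor(s_mag)).data
    return out[0] if squeeze else out


def csa_attention(e_mag: np.ndarray, s_mag: np.ndarray, csa: CSA) -> np.ndarray:
    """The row-stochastic attention matrix alpha itself."""
    e_mag = np.asarray(e_mag, dtype=np.float64)
    s_mag = np.asarray(s_mag, dtype=np.float64)
    squeeze = e_mag.ndim == 2
    if squeeze:
        e_mag, s_mag = e_mag[None], s_mag[None]
    out = csa.attention(Tensor(e_mag), Tensor(s_mag)).data
    return out[0] if squeeze else out


def wpp_forward(patch_grid: np.ndarray, beta: np.ndarray,
                lrelu_slope: float = 0.2) -> float:
    """Scalar score from a square patch grid with explicit weights beta."""
    grid = np.asarray(patch_grid, dtype=np.float64).squeeze()
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ValueError("patch grid must be square")
    k = grid.shape[0]
    beta = np.asarray(beta, dtype=np.float64)
    if beta.shape != (k * k + 1,):
        raise ValueError(f"beta must have length {k * k + 1}")
    wpp = WPP(k, lrelu_slope)
    wpp.beta.data = beta.astype(np.float64)
    return float(wpp(Tensor(grid.reshape(1, 1, k, k))).data[0])


def discriminator_forward(disc: Discriminator, e: np.ndarray, s: np.ndarray,
                          csa_enabled: bool = True) -> np.ndarray:
    return disc(e, s, use_csa=csa_enabled).data
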