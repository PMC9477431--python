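"""Wasserstein adversarial training with gradient penalty and L1 term.

The critic maximizes the score gap between real and generated pairs subject
to an approximate 1-Lipschitz constraint enforced by a gradient penalty on
pairs interpolated between real and generated depth spectra. The generator
minimizes the negated critic score plus lambda_l1 times the mean absolute
error against the real target. Training runs in two phases: the first
without the attention channel (fed as zeros), the second jointly with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .model import Discriminator, Generator, ModelConfig


@dataclass
class TrainingConfig:
    lambda_gp: float = 10.0
    lambda_l1: float = 10.0
    lr_g: float = 1e-5
    lr_d: float = 2e-5
    adam_beta1: float = 0.0
    adam_beta2: float = 0.99
    epochs_phase1: int = 80
    epochs_phase2: int = 40
    critic_steps: int = 1       # critic updates per generator update
    batch_size: int = 16
    seed: int = 0
    interpolate_condition: bool = False  # also mix the scalp side of the pair
    max_steps: int | None = None         # overall step cap (desk-scale runs)

    def __post_init__(self):
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ValueError("learning rates must be positive")
        if self.epochs_phase1 < 0 or self.epochs_phase2 < 0:
            raise ValueError("epochs must be non-negative")
        if self.critic_steps < 1 or self.batch_size < 1:
            raise ValueError("critic_steps and batch_size must be >= 1")


def l1_loss(s_real, s_fake) -> Tensor:
    """Mean absolute difference over the full tensors."""
    a = s_real if isinstance(s_real, Tensor) else Tensor(np.asarray(s_real, float))
    b = s_fake if isinstance(s_fake, Tensor) else Tensor(np.asarray(s_fake, float))
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return ad.tmean(ad.tabs(a - b))


def gradient_penalty(disc: Discriminator, e: np.ndarray, s_real: np.ndarray,
                     s_fake: np.ndarray, lambda_gp: float = 10.0,
                     rng: np.random.Generator | None = None,
                     use_csa: bool = True,
                     interpolate_condition: bool = False,
                     e_fake: np.ndarray | None = None) -> Tensor:
    """Two-sided gradient penalty on interpolated critic inputs.

    The depth spectra are mixed with a per-sample uniform epsilon; the scalp
    condition is fixed by default (set ``interpolate_condition`` to mix it
    with ``e_fake`` as well). The gradient is taken over the full critic
    input — both scalp and depth channels, through the attention path.
    """
    rng = rng or np.random.default_rng()
    e = np.asarray(e, dtype=np.float64)
    s_real = np.asarray(s_real, dtype=np.float64)
    s_fake = np.asarray(s_fake, dtype=np.float64)
    if s_real.shape != s_fake.shape:
        raise ValueError("real and fake pairs must share a shape")
    n = s_real.shape[0]
    eps = rng.uniform(size=(n, 1, 1, 1))
    s_hat = eps * s_real + (1 - eps) * s_fake
    if interpolate_condition and e_fake is not None:
        e_hat = eps * e + (1 - eps) * np.asarray(e_fake, dtype=np.float64)
    else:
        e_hat = e
    x = Tensor(np.concatenate([e_hat, s_hat], axis=1), requires_grad=True)
    score = ad.tsum(disc.critic(x, use_csa=use_csa))
    (gx,) = ad.grad(score, [x])
    sq = ad.tsum(gx * gx, axis=(1, 2, 3))
    norm = ad.tsqrt(sq + 1e-12)
    return ad.tmean(ad.pow_const(norm - 1.0, 2.0)) * lambda_gp


@dataclass
class History:
    steps: list[dict] = field(default_factory=list)
    val_l1: list[float] = field(default_factory=list)
    best_val_l1: float = np.inf

    def log(self, **kwargs):
        self.steps.append(kwargs)


def _as_batches(n_items: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n_items)
    for i in range(0, n_items, batch_size):
        batch = order[i:i + batch_size]
        if len(batch) > 0:
            yield batch


def _validate_l1(gen: Generator, e_val: np.ndarray, s_val: np.ndarray) -> float:
    out = gen(e_val).data
    return float(np.mean(np.abs(out - s_val)))


def train(e_data: np.ndarray, s_data: np.ndarray, cfg: TrainingConfig,
          model_cfg: ModelConfig | None = None,
          val: tuple[np.ndarray, np.ndarray] | None = None
          ) -> tuple[Generator, Discriminator, History]:
    """Adversarial training over aligned (scalp, depth) spectral tensors.

    ``e_data``/``s_data`` are (N, 2, size, size) arrays in the network range.
    Deterministic given ``cfg.seed`` under single-threaded execution. Raises
    on non-finite losses. Returns the generator (restored to its best
    validation-L1 checkpoint when a validation split is given), the critic,
    and the step-wise loss history.
    """
    e_data = np.asarray(e_data, dtype=np.float64)
    s_data = np.asarray(s_data, dtype=np.float64)
    if e_data.shape != s_data.shape or e_data.ndim != 4:
        raise ValueError("expected matching (N, 2, size, size) arrays")
    if e_data.shape[0] == 0:
        raise ValueError("empty training set")
    model_cfg = model_cfg or ModelConfig(size=e_data.shape[-1])

    rng = np.random.default_rng(cfg.seed)
    gen = Generator(model_cfg, seed=cfg.seed)
    disc = Discriminator(model_cfg, seed=cfg.seed + 1)
    opt_g = nn.Adam(gen.parameters(), cfg.lr_g, cfg.adam_beta1, cfg.adam_beta2)
    opt_d = nn.Adam(disc.parameters(), cfg.lr_d, cfg.adam_beta1, cfg.adam_beta2)

    history = History()
    best_state = None
    step = 0
    done = False

    phases = [(cfg.epochs_phase1, False), (cfg.epochs_phase2, True)]
    for n_epochs, use_csa in phases:
        if done:
            break
        for _ in range(n_epochs):
            if done:
                break
            for batch in _as_batches(e_data.shape[0], cfg.batch_size, rng):
                e_b, s_b = e_data[batch], s_data[batch]

                # --- critic update -----------------------------------------
                fake = gen(e_b).data  # detached: critic sees fixed samples
                d_real = ad.tmean(disc(e_b, s_b, use_csa=use_csa))
                d_fake = ad.tmean(disc(e_b, fake, use_csa=use_csa))
                gp = gradient_penalty(disc, e_b, s_b, fake,
                                      lambda_gp=cfg.lambda_gp, rng=rng,
                                      use_csa=use_csa,
                                      interpolate_condition=cfg.interpolate_condition)
                d_loss = d_fake - d_real + gp
                d_params = disc.parameters()
                opt_d.step(ad.grad(d_loss, d_params))

                # --- generator update --------------------------------------
                g_loss_val = np.nan
                l1_val = np.nan
                if step % cfg.critic_steps == 0:
                    g_out = gen(e_b)
                    adv = ad.tmean(disc(e_b, g_out, use_csa=use_csa))
                    l1 = l1_loss(Tensor(s_b), g_out)
                    g_loss = (-1.0) * adv + cfg.lambda_l1 * l1
                    opt_g.step(ad.grad(g_loss, gen.parameters()))
                    g_loss_val = g_loss.item()
                    l1_val = l1.item()

                w_dist = d_real.item() - d_fake.item()
                vals = (d_loss.item(), gp.item(), g_loss_val)
                if not np.isfinite([v for v in vals if not np.isnan(v)]).all():
                    raise RuntimeError(
                        f"non-finite loss at step {step}: d={vals[0]}, "
                        f"gp={vals[1]}, g={vals[2]}")
                history.log(step=step, phase=2 if use_csa else 1,
                            d_loss=d_loss.item(), wgan=w_dist, gp=gp.item(),
                            g_loss=g_loss_val, l1=l1_val)
                step += 1
                if cfg.max_steps is not None and step >= cfg.max_steps:
                    done = True
                    break
            if val is not None:
                v = _validate_l1(gen, *val)
                history.val_l1.append(v)
                if v < history.best_val_l1:
                    history.best_val_l1 = v
                    best_state = gen.state_dict()

    if best_state is not None:
        gen.load_state_dict(best_state)
    return gen, disc, history
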