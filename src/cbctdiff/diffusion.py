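"""Forward diffusion, training objective, and conditional sampling.

The forward process gradually replaces image content with Gaussian noise
according to a :class:`~cbctdiff.schedules.NoiseSchedule`; a noise-
prediction network ``eps_theta(x_t, y0, t)`` is trained to invert it with
the guiding CBCT ``y0`` concatenated as a second input channel at every
step (channel conditioning).

Two samplers are provided:

``sample_original``
    Classic DDPM ancestral sampling: start at pure noise ``x_T ~ N(0, I)``
    and denoise for ``T`` steps.  The conditioning channel is fed a neutral
    all-zeros image so the same 2-channel network serves both entry points.

``sample_noised_conditioned``
    The few-shot variant: the guiding CBCT is itself pushed through the
    forward process to an intermediate timestep ``t_con`` and ancestral
    sampling starts there, with the clean CBCT still concatenated at every
    step.  Because a shared noise realisation drives a pCT and its CBCT to
    the same neighbourhood of latent space (their difference shrinks as
    ``sqrt(alpha_bar_t)``), a partially noised CBCT is a good stand-in for
    a partially denoised CT — so most of the anatomy survives while CBCT-
    specific artifacts are destroyed and re-synthesised as CT content.

``t_con`` trades anatomy preservation against correction opportunity:
``t_con = T`` degenerates to channel-conditioned sampling from pure noise,
``t_con = 0`` returns the CBCT unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .schedules import NoiseSchedule
from .timesteps import TimestepDistribution, sample_timesteps
from .nn.autodiff import Tensor, backward, mse_loss
from .nn.optim import Adam


class DiffusionError(ValueError):
    """Contract violation in a diffusion operation."""


class NoisePredictor(Protocol):
    """Anything exposing ``predict(x_t, y0, t) -> eps_hat``."""

    def predict(self, x_t: np.ndarray, y0: np.ndarray, t) -> np.ndarray: ...


@dataclass(frozen=True)
class SamplingConfig:
    """Options for noised-conditioned sampling.

    ``t_con = 0`` is the degenerate case (return the conditioning image
    unchanged); ``stochastic_z=False`` zeroes the per-step noise injection,
    making the reverse trajectory deterministic.
    """

    t_con: int
    stochastic_z: bool = True
    seed: int | None = None


# ---------------------------------------------------------------------------
# forward process
# ---------------------------------------------------------------------------

def forward_diffuse(
    x0: np.ndarray, t: int, eps: np.ndarray, schedule: NoiseSchedule
) -> np.ndarray:
    """One-shot jump to timestep ``t``:
    ``x_t = sqrt(alpha_bar_t) x0 + sqrt(1 - alpha_bar_t) eps``."""
    x0 = np.asarray(x0)
    eps = np.asarray(eps)
    if x0.shape != eps.shape:
        raise DiffusionError(f"shape mismatch: x0 {x0.shape} vs eps {eps.shape}")
    ab = schedule.alpha_bar_at(t)
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def forward_step(
    x_prev: np.ndarray, t: int, schedule: NoiseSchedule, rng: np.random.Generator
) -> np.ndarray:
    """Single Markov step ``q(x_t | x_{t-1}) = N(sqrt(1-beta_t) x_{t-1}, beta_t I)``."""
    if not 1 <= t <= schedule.T:
        raise DiffusionError(f"timestep {t} outside [1, {schedule.T}]")
    beta = schedule.beta[t]
    return np.sqrt(1.0 - beta) * np.asarray(x_prev) + np.sqrt(beta) * rng.standard_normal(
        np.shape(x_prev)
    )


# ---------------------------------------------------------------------------
# training objective
# ---------------------------------------------------------------------------

def training_loss(
    denoiser: NoisePredictor,
    x0: np.ndarray,
    y0: np.ndarray,
    t: int,
    eps: np.ndarray,
    schedule: NoiseSchedule,
) -> float:
    """Mean squared error ``||eps - eps_theta(x_t, y0, t)||^2 / N`` with
    ``x_t`` from :func:`forward_diffuse`."""
    if np.shape(x0) != np.shape(y0):
        raise DiffusionError("x0 and y0 must share shape")
    x_t = forward_diffuse(x0, t, eps, schedule)
    eps_hat = denoiser.predict(x_t, y0, t)
    return float(np.mean((np.asarray(eps) - eps_hat) ** 2))


# ---------------------------------------------------------------------------
# reverse process
# ---------------------------------------------------------------------------

def reverse_step(
    eps_hat: np.ndarray,
    x_t: np.ndarray,
    t: int,
    schedule: NoiseSchedule,
    z: np.ndarray | None = None,
) -> np.ndarray:
    """Ancestral DDPM update
    ``x_{t-1} = (x_t - (1-alpha_t)/sqrt(1-alpha_bar_t) eps_hat)/sqrt(alpha_t)
    + sigma_t z``.

    ``z`` must be zero (or None) at ``t = 1``.
    """
    if not 1 <= t <= schedule.T:
        raise DiffusionError(f"timestep {t} outside [1, {schedule.T}]")
    if t == 1 and z is not None and np.any(np.asarray(z)):
        raise DiffusionError("z must be 0 at t = 1")
    alpha = schedule.alpha[t]
    ab = schedule.alpha_bar[t]
    mean = (np.asarray(x_t) - (1.0 - alpha) / np.sqrt(1.0 - ab) * np.asarray(eps_hat)) / np.sqrt(
        alpha
    )
    if z is None:
        return mean
    return mean + schedule.sigma[t] * np.asarray(z)


def _ancestral_loop(
    denoiser: NoisePredictor,
    x: np.ndarray,
    y0: np.ndarray,
    t_start: int,
    schedule: NoiseSchedule,
    rng: np.random.Generator | None,
    stochastic_z: bool,
) -> np.ndarray:
    for t in range(t_start, 0, -1):
        eps_hat = denoiser.predict(x, y0, t)
        if stochastic_z and t > 1:
            z = rng.standard_normal(x.shape)
        else:
            z = None
        x = reverse_step(eps_hat, x, t, schedule, z)
    return x


def sample_original(
    denoiser: NoisePredictor,
    schedule: NoiseSchedule,
    shape: tuple[int, ...],
    rng: np.random.Generator,
    stochastic_z: bool = True,
) -> np.ndarray:
    """Unconditional-entry sampling: ``x_T ~ N(0, I)`` then ``T`` reverse
    steps, with an all-zeros conditioning channel."""
    x = rng.standard_normal(shape)
    y0 = np.zeros(shape)
    return _ancestral_loop(denoiser, x, y0, schedule.T, schedule, rng, stochastic_z)


def sample_noised_conditioned(
    denoiser: NoisePredictor,
    y0: np.ndarray,
    schedule: NoiseSchedule,
    cfg: SamplingConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Channel- and noised-conditioned sampling from a guiding image.

    ``y0`` (a normalized CBCT slice, or a batch of them) is diffused to
    ``cfg.t_con`` with a fresh noise draw, then denoised back to ``t = 0``
    with ``y0`` concatenated at every step.
    """
    y0 = np.asarray(y0)
    if not 0 <= cfg.t_con <= schedule.T:
        raise DiffusionError(f"t_con {cfg.t_con} outside [0, {schedule.T}]")
    if cfg.t_con == 0:
        return y0.copy()
    eps = rng.standard_normal(y0.shape)
    x = forward_diffuse(y0, cfg.t_con, eps, schedule)
    return _ancestral_loop(denoiser, x, y0, cfg.t_con, schedule, rng, cfg.stochastic_z)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    steps: int = 2000
    batch_size: int = 8
    lr: float = 1e-4
    lr_final: float | None = None  # cosine-decay target; None = constant lr
    n_bands: int = 10  # timestep bands for loss bookkeeping (deciles of T)

    def lr_at(self, step: int) -> float:
        if self.lr_final is None:
            return self.lr
        frac = (1.0 + np.cos(np.pi * step / max(self.steps - 1, 1))) / 2.0
        return self.lr_final + (self.lr - self.lr_final) * frac


@dataclass
class LossHistory:
    """Per-gradient-step losses tagged with the timestep band they probed.

    Bands partition ``{1..T}`` into ``n_bands`` equal intervals; band ``k``
    (1-based) covers ``((k-1) T / n, k T / n]``.
    """

    T: int
    n_bands: int
    steps: list[int] = field(default_factory=list)
    timesteps: list[int] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)

    def band_of(self, t: int) -> int:
        return int(np.ceil(t * self.n_bands / self.T))

    def record(self, step: int, t: int, loss: float) -> None:
        self.steps.append(step)
        self.timesteps.append(int(t))
        self.losses.append(float(loss))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"step": self.steps, "t": self.timesteps, "loss": self.losses}
        )
        df["band"] = np.ceil(df["t"] * self.n_bands / self.T).astype(int)
        return df

    def band_mean_loss(
        self, band: int, step_range: tuple[int, int] | None = None
    ) -> float:
        """Mean loss of one band, optionally restricted to [start, stop) steps."""
        df = self.to_dataframe()
        sel = df["band"] == band
        if step_range is not None:
            sel &= (df["step"] >= step_range[0]) & (df["step"] < step_range[1])
        sub = df.loc[sel, "loss"]
        if sub.empty:
            raise DiffusionError(f"no recorded losses in band {band}")
        return float(sub.mean())


def _pair_arrays(sample) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(sample, "pct"):
        if getattr(sample, "unit_tag", "normalized") != "normalized":
            raise DiffusionError("training pairs must be in normalized units")
        return sample.pct, sample.cbct
    x0, y0 = sample
    return np.asarray(x0), np.asarray(y0)


def train(
    denoiser,
    dataset: Sequence,
    schedule: NoiseSchedule,
    sampler: TimestepDistribution,
    config: TrainConfig,
    rng: np.random.Generator,
    callback=None,
) -> LossHistory:
    """Run the conditional DDPM training loop.

    Each step draws a batch of (pCT, CBCT) pairs, a timestep per pair from
    ``sampler``, and fresh noise; takes one Adam step on the noise-
    prediction MSE; and records every per-sample loss with its timestep so
    band-wise convergence can be inspected afterwards.

    ``dataset`` holds normalized-unit pairs: either
    :class:`~cbctdiff.phantoms.PairedSample` objects or (x0, y0) tuples.
    """
    if len(dataset) == 0:
        raise DiffusionError("dataset must be non-empty")
    if sampler.T != schedule.T:
        raise DiffusionError("sampler and schedule disagree on T")
    pairs = [_pair_arrays(s) for s in dataset]
    x0s = np.stack([p[0] for p in pairs]).astype(np.float32)
    y0s = np.stack([p[1] for p in pairs]).astype(np.float32)

    opt = Adam(denoiser.parameters(), lr=config.lr)
    history = LossHistory(T=schedule.T, n_bands=config.n_bands)
    sqrt_ab = np.sqrt(schedule.alpha_bar)
    sqrt_1mab = np.sqrt(1.0 - schedule.alpha_bar)

    for step in range(config.steps):
        idx = rng.integers(0, len(pairs), size=config.batch_size)
        ts = sample_timesteps(sampler, config.batch_size, rng)
        x0 = x0s[idx][:, None]  # (B, 1, H, W)
        y0 = y0s[idx][:, None]
        eps = rng.standard_normal(x0.shape).astype(np.float32)
        a = sqrt_ab[ts][:, None, None, None].astype(np.float32)
        b = sqrt_1mab[ts][:, None, None, None].astype(np.float32)
        x_t = a * x0 + b * eps

        opt.lr = config.lr_at(step)
        out = denoiser.forward(Tensor(x_t), Tensor(y0), ts)
        loss = mse_loss(out, eps)
        backward(loss)
        opt.step()
        opt.zero_grad()

        per_sample = ((out.data - eps) ** 2).mean(axis=(1, 2, 3))
        for t_i, l_i in zip(ts, per_sample):
            history.record(step, t_i, l_i)
        if callback is not None:
            callback(step, float(loss.data))

    return history
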