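"""Training-time timestep distributions.

During training each gradient step draws a timestep ``t`` from ``{1..T}``.
The classic choice is uniform.  Because the low-timestep regime (where the
image is nearly clean and fine detail is being formed) is the slowest part
of the denoising task to converge, two alternatives weight the draw toward
small ``t``:

``exponential``
    weight(t) proportional to ``exp(-t / tau)`` with decay scale ``tau``
    (default ``T / 4``).
``triangular``
    weight(t) proportional to ``T - t + 1`` — a linear ramp peaking at
    ``t = 1``.

Draws use inverse-CDF lookup on the tabulated pmf, so every kind is exact
and reproducible from a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

SamplerKind = Literal["uniform", "exponential", "triangular"]


class SamplerError(ValueError):
    """Invalid timestep-distribution parameters."""


@dataclass(frozen=True)
class TimestepDistribution:
    """A sampling law over timesteps ``{1..T}``."""

    kind: str
    T: int
    tau: float | None = None  # exponential decay scale; ignored otherwise

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "exponential", "triangular"):
            raise SamplerError(f"unknown sampler kind {self.kind!r}")
        if self.T < 1:
            raise SamplerError(f"T must be >= 1, got {self.T}")
        if self.kind == "exponential":
            tau = self.T / 4 if self.tau is None else self.tau
            if tau <= 0:
                raise SamplerError(f"tau must be > 0, got {tau}")
            object.__setattr__(self, "tau", float(tau))


def pmf(dist: TimestepDistribution) -> np.ndarray:
    """Probability of each timestep, as a length-``T`` vector for ``t = 1..T``."""
    T = dist.T
    t = np.arange(1, T + 1, dtype=float)
    if dist.kind == "uniform":
        w = np.ones(T)
    elif dist.kind == "exponential":
        # subtract t=1 in the exponent for numerical safety at large T/tau
        w = np.exp(-(t - 1.0) / dist.tau)
    else:  # triangular
        w = T - t + 1.0
    return w / w.sum()


def sample_timesteps(
    dist: TimestepDistribution, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. timesteps in ``{1..T}`` by inverse-CDF lookup."""
    if n < 1:
        raise SamplerError(f"n must be >= 1, got {n}")
    cdf = np.cumsum(pmf(dist))
    cdf[-1] = 1.0  # guard against cumulative rounding
    u = rng.random(n)
    return np.searchsorted(cdf, u, side="right").astype(np.int64) + 1
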