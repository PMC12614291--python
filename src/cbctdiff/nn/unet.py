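"""Conditional noise-prediction U-Net.

The network implements the denoiser contract of conditional DDPM training:
input is the noisy CT sample concatenated with the noise-free guiding CBCT
along the channel axis (2 channels in), output is the predicted noise
(1 channel out), and the timestep enters through a sinusoidal embedding
added per residual block.  Spatial self-attention is applied at
configurable resolution levels (by default only the deepest one).

The architecture is fully size-configurable: the defaults are a toy scale
that trains on a CPU in minutes, while :func:`paper_scale_config` returns a
6-level, ~1e8-parameter configuration of the same family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class DenoiserConfigError(ValueError):
    """Invalid denoiser configuration."""


@dataclass(frozen=True)
class DenoiserConfig:
    in_channels: int = 2
    out_channels: int = 1
    depth: int = 3
    blocks_per_level: int = 2
    base_width: int = 16
    channel_mults: tuple[int, ...] | None = None  # default: 2**level capped at max_mult
    max_mult: int = 8
    attention_levels: tuple[int, ...] = field(default=None)  # default: deepest level
    time_embedding_dim: int = 64
    norm_groups: int = 8

    def __post_init__(self):
        if self.depth < 1:
            raise DenoiserConfigError(f"depth must be >= 1, got {self.depth}")
        if self.blocks_per_level < 1 or self.base_width < 1:
            raise DenoiserConfigError("blocks_per_level and base_width must be >= 1")
        if self.channel_mults is None:
            mults = tuple(min(2**i, self.max_mult) for i in range(self.depth))
            object.__setattr__(self, "channel_mults", mults)
        elif len(self.channel_mults) != self.depth:
            raise DenoiserConfigError("channel_mults length must equal depth")
        if self.attention_levels is None:
            object.__setattr__(self, "attention_levels", (self.depth - 1,))

    @property
    def level_widths(self) -> tuple[int, ...]:
        return tuple(self.base_width * m for m in self.channel_mults)


def paper_scale_config() -> DenoiserConfig:
    """Six resolution levels, two residual blocks per level, attention at
    one level — on the order of 1e8 parameters (suitable for 256x256
    inputs; not exercised by the CPU test suite)."""
    return DenoiserConfig(depth=6, blocks_per_level=2, base_width=96,
                          attention_levels=(5,), time_embedding_dim=256)


def _ngroups(channels: int, preferred: int) -> int:
    g = min(preferred, channels)
    while channels % g:
        g -= 1
    return g


class _Params:
    """Parameter store; creates named leaf tensors with seeded init."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.tensors: dict[str, Tensor] = {}

    def conv(self, name: str, o: int, c: int, k: int, scale: float = 1.0):
        fan_in = c * k * k
        shape = (o, c, k, k) if k == 3 else (o, c)
        w = scale * self.rng.standard_normal(shape).astype(np.float32) / math.sqrt(fan_in)
        b = np.zeros(o, dtype=np.float32)
        self.tensors[f"{name}.w"] = Tensor(w, requires_grad=True)
        self.tensors[f"{name}.b"] = Tensor(b, requires_grad=True)
        return self.tensors[f"{name}.w"], self.tensors[f"{name}.b"]

    def linear(self, name: str, d_in: int, d_out: int):
        w = self.rng.standard_normal((d_in, d_out)).astype(np.float32) / math.sqrt(d_in)
        b = np.zeros(d_out, dtype=np.float32)
        self.tensors[f"{name}.w"] = Tensor(w, requires_grad=True)
        self.tensors[f"{name}.b"] = Tensor(b, requires_grad=True)
        return self.tensors[f"{name}.w"], self.tensors[f"{name}.b"]

    def norm(self, name: str, c: int):
        self.tensors[f"{name}.g"] = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.tensors[f"{name}.b"] = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        return self.tensors[f"{name}.g"], self.tensors[f"{name}.b"]


class _ResBlock:
    def __init__(self, p: _Params, name: str, c_in: int, c_out: int, emb_dim: int, groups: int):
        self.g1 = p.norm(f"{name}.gn1", c_in)
        self.c1 = p.conv(f"{name}.conv1", c_out, c_in, 3)
        self.emb = p.linear(f"{name}.emb", emb_dim, c_out)
        self.g2 = p.norm(f"{name}.gn2", c_out)
        self.c2 = p.conv(f"{name}.conv2", c_out, c_out, 3)
        self.skip = p.conv(f"{name}.skip", c_out, c_in, 1) if c_in != c_out else None
        self.ng1 = _ngroups(c_in, groups)
        self.ng2 = _ngroups(c_out, groups)

    def __call__(self, x: Tensor, emb: Tensor) -> Tensor:
        h = ad.conv3x3(ad.silu(ad.group_norm(x, *self.g1, self.ng1)), *self.c1)
        t = ad.add(ad.matmul(emb, self.emb[0]), self.emb[1])  # (N, c_out)
        h = ad.add_channel_bias(h, t)
        h = ad.conv3x3(ad.silu(ad.group_norm(h, *self.g2, self.ng2)), *self.c2)
        sk = ad.conv1x1(x, *self.skip) if self.skip else x
        return ad.add(h, sk)


class _Attention:
    """Single-head spatial self-attention over flattened pixels."""

    def __init__(self, p: _Params, name: str, c: int, groups: int):
        self.gn = p.norm(f"{name}.gn", c)
        self.q = p.linear(f"{name}.q", c, c)
        self.k = p.linear(f"{name}.k", c, c)
        self.v = p.linear(f"{name}.v", c, c)
        self.o = p.linear(f"{name}.o", c, c)
        self.ng = _ngroups(c, groups)
        self.scale = Tensor(np.float32(1.0 / math.sqrt(c)))

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        hn = ad.group_norm(x, *self.gn, self.ng)
        tok = ad.swap_last2(ad.reshape(hn, (n, c, h * w)))  # (N, HW, C)
        q = ad.add(ad.matmul(tok, self.q[0]), self.q[1])
        k = ad.add(ad.matmul(tok, self.k[0]), self.k[1])
        v = ad.add(ad.matmul(tok, self.v[0]), self.v[1])
        att = ad.softmax(ad.mul(ad.matmul(q, ad.swap_last2(k)), self.scale))
        out = ad.add(ad.matmul(ad.matmul(att, v), self.o[0]), self.o[1])
        out = ad.reshape(ad.swap_last2(out), (n, c, h, w))
        return ad.add(x, out)


def _sinusoidal_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    half = dim // 2
    freqs = np.exp(-math.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t[:, None].astype(np.float64) * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1).astype(np.float32)


class Denoiser:
    """epsilon_theta(x_t, y0, t): 2-channel-in, 1-channel-out U-Net."""

    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator):
        self.cfg = cfg
        p = _Params(rng)
        widths = cfg.level_widths
        d, e = cfg.time_embedding_dim, 2 * cfg.time_embedding_dim
        self.t1 = p.linear("time.l1", d, e)
        self.t2 = p.linear("time.l2", e, e)
        self.stem = p.conv("stem", widths[0], cfg.in_channels, 3)

        self.down: list[list] = []
        c = widths[0]
        for i in range(cfg.depth):
            blocks = []
            for j in range(cfg.blocks_per_level):
                blocks.append(_ResBlock(p, f"down{i}.res{j}", c, widths[i], e, cfg.norm_groups))
                c = widths[i]
            if i in cfg.attention_levels:
                blocks.append(_Attention(p, f"down{i}.attn", c, cfg.norm_groups))
            self.down.append(blocks)

        self.mid1 = _ResBlock(p, "mid.res1", c, c, e, cfg.norm_groups)
        self.mid_attn = _Attention(p, "mid.attn", c, cfg.norm_groups)
        self.mid2 = _ResBlock(p, "mid.res2", c, c, e, cfg.norm_groups)

        self.up: list[list] = []
        for i in reversed(range(cfg.depth)):
            blocks = []
            cin = c + widths[i]  # skip concatenation
            for j in range(cfg.blocks_per_level):
                blocks.append(_ResBlock(p, f"up{i}.res{j}", cin, widths[i], e, cfg.norm_groups))
                cin = widths[i]
            if i in cfg.attention_levels:
                blocks.append(_Attention(p, f"up{i}.attn", widths[i], cfg.norm_groups))
            self.up.append(blocks)
            c = widths[i]

        self.out_gn = p.norm("out.gn", c)
        self.out_ng = _ngroups(c, cfg.norm_groups)
        # near-zero output head: starts close to the identity denoising
        # target while keeping the map sensitive to all inputs
        self.out_conv = p.conv("out.conv", cfg.out_channels, c, 3, scale=0.01)
        self.params = p.tensors

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def param_count(self) -> int:
        return int(sum(t.data.size for t in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self.params) ^ set(state)
        if missing:
            raise DenoiserConfigError(f"state dict mismatch: {sorted(missing)[:5]}")
        for k, v in state.items():
            if self.params[k].data.shape != v.shape:
                raise DenoiserConfigError(f"shape mismatch for {k}")
            self.params[k].data = np.asarray(v, dtype=np.float32).copy()

    def zero_grad(self) -> None:
        for t in self.parameters():
            t.grad = None

    # -- forward ------------------------------------------------------------

    def _check_spatial(self, h: int, w: int) -> None:
        f = 2 ** (self.cfg.depth - 1)
        if h % f or w % f:
            raise DenoiserConfigError(
                f"spatial size {h}x{w} not divisible by 2^(depth-1) = {f}"
            )

    def forward(self, x_t: Tensor, y0: Tensor, t: np.ndarray) -> Tensor:
        """Graph-building forward pass; inputs are (N, 1, H, W) tensors."""
        n, _, h, w = x_t.shape
        self._check_spatial(h, w)
        emb = Tensor(_sinusoidal_embedding(t, self.cfg.time_embedding_dim))
        emb = ad.silu(ad.add(ad.matmul(emb, self.t1[0]), self.t1[1]))
        emb = ad.add(ad.matmul(emb, self.t2[0]), self.t2[1])

        x = ad.conv3x3(ad.concat_channels(x_t, y0), *self.stem)
        skips = []
        for i, blocks in enumerate(self.down):
            for blk in blocks:
                x = blk(x, emb) if isinstance(blk, _ResBlock) else blk(x)
            skips.append(x)
            if i < self.cfg.depth - 1:
                x = ad.avg_pool2(x)

        x = self.mid1(x, emb)
        x = self.mid_attn(x)
        x = self.mid2(x, emb)

        for j, blocks in enumerate(self.up):
            level = self.cfg.depth - 1 - j
            if level < self.cfg.depth - 1:
                x = ad.upsample2(x)
            x = ad.concat_channels(x, skips[level])
            for blk in blocks:
                x = blk(x, emb) if isinstance(blk, _ResBlock) else blk(x)

        x = ad.silu(ad.group_norm(x, *self.out_gn, self.out_ng))
        return ad.conv3x3(x, *self.out_conv)

    def predict(self, x_t: np.ndarray, y0: np.ndarray, t) -> np.ndarray:
        """Inference path on plain arrays; see :func:`predict_noise`."""
        x_t = np.asarray(x_t, dtype=np.float32)
        y0 = np.asarray(y0, dtype=np.float32)
        if x_t.shape != y0.shape:
            raise ValueError(f"shape mismatch: x_t {x_t.shape} vs y0 {y0.shape}")
        squeeze = x_t.ndim == 2
        if squeeze:
            x_t, y0 = x_t[None], y0[None]
        tarr = np.full(x_t.shape[0], t, dtype=np.int64) if np.isscalar(t) else np.asarray(t)
        if np.any(tarr < 1):
            raise ValueError("timesteps must be >= 1")
        out = self.forward(Tensor(x_t[:, None]), Tensor(y0[:, None]), tarr)
        eps = out.data[:, 0]
        return eps[0] if squeeze else eps


def build_denoiser(cfg: DenoiserConfig, rng: np.random.Generator) -> Denoiser:
    """Initialise a :class:`Denoiser` with seeded weights."""
    return Denoiser(cfg, rng)


def predict_noise(denoiser: Denoiser, x_t: np.ndarray, y0: np.ndarray, t) -> np.ndarray:
    """Predicted noise for (noisy sample, conditioning image, timestep).

    Accepts a single (H, W) slice or an (N, H, W) batch; ``t`` may be a
    scalar or a per-sample vector.  Deterministic given fixed weights.
    """
    return denoiser.predict(x_t, y0, t)


def count_parameters(cfg: DenoiserConfig) -> int:
    """Parameter count of a config, computed without training-scale cost
    (instantiates with a fixed seed; weights are discarded)."""
    return Denoiser(cfg, np.random.default_rng(0)).param_count()
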