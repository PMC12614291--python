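"""Experiment orchestration: configuration, runs, and reproduction sweeps.

A run is fully described by an :class:`ExperimentConfig` (strictly
validated YAML) and its global seed, which fans out to independent named
sub-seeds for data generation, weight initialisation, training and
sampling so each stage can be varied in isolation.  The harnesses here
reproduce the study designs that matter for the method:

* :func:`run_experiment` — generate paired phantom slices, train the
  conditional denoiser, sample synthetic CTs at each requested ``t_con``,
  and score them against the planning CTs inside the FOV mask;
* :func:`sweep_tcon` — the schedule-by-``t_con`` grid (one model per
  schedule kind, one row per ``t_con``);
* :func:`sensitivity_sweep` — retrain with progressively fewer training
  pairs, everything else held constant.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import io as cio
from .diffusion import SamplingConfig, TrainConfig, sample_noised_conditioned, train
from .metrics import aggregate_metrics, evaluate_pairs
from .nn.unet import Denoiser, DenoiserConfig
from .phantoms import (
    AnatomySpec,
    DegradationSpec,
    PairedSample,
    fov_mask,
    make_pair_dataset,
    preprocess,
    to_hu,
)
from .schedules import make_schedule
from .timesteps import TimestepDistribution


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataBlock(_Block):
    n_pairs: int = 220
    n_val: int = 20
    shape: int = 32
    bias_amplitude: float = 60.0
    streak_count: int = 6
    streak_intensity: float = 120.0
    noise_sd: float = 20.0
    fov_radius_frac: float = 0.9
    shift_px: tuple[int, int] = (1, 1)
    contour_scale: float = 0.98

    def degradation_spec(self) -> DegradationSpec:
        return DegradationSpec(
            bias_amplitude=self.bias_amplitude,
            streak_count=self.streak_count,
            streak_intensity=self.streak_intensity,
            noise_sd=self.noise_sd,
            fov_radius_frac=self.fov_radius_frac,
            shift_px=tuple(self.shift_px),
            contour_scale=self.contour_scale,
        )


class ScheduleBlock(_Block):
    kind: Literal["linear", "cosine", "sigmoid"] = "cosine"
    T: int = 1000
    beta_min: float = 1e-4
    beta_max: float = 0.02
    sigma_mode: Literal["beta", "beta_tilde"] = "beta"
    cosine_beta: bool = False

    def make(self, kind: str | None = None):
        return make_schedule(
            kind or self.kind, self.T, self.beta_min, self.beta_max,
            sigma_mode=self.sigma_mode, cosine_beta=self.cosine_beta,
        )


class ModelBlock(_Block):
    depth: int = 3
    blocks_per_level: int = 1
    base_width: int = 16
    time_embedding_dim: int = 64

    def denoiser_config(self) -> DenoiserConfig:
        return DenoiserConfig(
            depth=self.depth,
            blocks_per_level=self.blocks_per_level,
            base_width=self.base_width,
            time_embedding_dim=self.time_embedding_dim,
        )


class TrainBlock(_Block):
    steps: int = 3000
    batch_size: int = 8
    lr: float = 1e-3
    lr_final: float | None = 1e-4
    timestep_sampler: Literal["uniform", "exponential", "triangular"] = "uniform"
    tau: float | None = None


class SampleBlock(_Block):
    t_con: tuple[int, ...] = (1000, 800)
    stochastic_z: bool = True

    @field_validator("t_con")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("t_con list must be non-empty")
        return v


class EvalBlock(_Block):
    mask_radius_frac: float | None = None  # default: the CBCT FOV radius
    data_range: float = 4000.0
    hist_lower_trunc: float = -950.0


class ExperimentConfig(_Block):
    seed: int = 0
    data: DataBlock = DataBlock()
    schedule: ScheduleBlock = ScheduleBlock()
    model: ModelBlock = ModelBlock()
    train: TrainBlock = TrainBlock()
    sample: SampleBlock = SampleBlock()
    eval: EvalBlock = EvalBlock()

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sub_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("data", "init", "train", "sample")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _generate_split(
    cfg: ExperimentConfig, rng: np.random.Generator
) -> tuple[list[PairedSample], list[PairedSample]]:
    pairs = make_pair_dataset(
        cfg.data.n_pairs, AnatomySpec(), cfg.data.degradation_spec(), rng,
        shape=(cfg.data.shape, cfg.data.shape),
    )
    if cfg.data.n_val >= cfg.data.n_pairs:
        raise ValueError("n_val must be smaller than n_pairs")
    return pairs[: -cfg.data.n_val], pairs[-cfg.data.n_val :]


def _sample_batch(denoiser, val_norm_cbct, schedule, t_con, stochastic_z, rng):
    scfg = SamplingConfig(t_con=t_con, stochastic_z=stochastic_z)
    out = sample_noised_conditioned(denoiser, val_norm_cbct, schedule, scfg, rng)
    return to_hu(np.clip(out, -1.0, 1.0))


def _evaluate_tcons(denoiser, schedule, val, cfg, rng) -> dict[int, pd.DataFrame]:
    """Sample sCTs for each t_con and score per slice (HU space)."""
    shape = (cfg.data.shape, cfg.data.shape)
    radius = cfg.eval.mask_radius_frac or cfg.data.fov_radius_frac
    mask = fov_mask(shape, radius)
    cbct_norm = np.stack([preprocess(s.cbct) for s in val])
    pcts = [s.pct for s in val]
    cbcts = [s.cbct for s in val]
    per_tcon = {}
    scts = {}
    for t_con in cfg.sample.t_con:
        sct = _sample_batch(
            denoiser, cbct_norm, schedule, t_con, cfg.sample.stochastic_z, rng
        )
        scts[t_con] = sct
        per_tcon[t_con] = evaluate_pairs(
            list(sct), pcts, cbcts, mask, data_range=cfg.eval.data_range
        )
    return per_tcon, scts


def _train_model(cfg: ExperimentConfig, train_pairs, schedule, rngs):
    denoiser = Denoiser(cfg.model.denoiser_config(), rngs["init"])
    sampler = TimestepDistribution(
        cfg.train.timestep_sampler, schedule.T, tau=cfg.train.tau
    )
    tconf = TrainConfig(
        steps=cfg.train.steps, batch_size=cfg.train.batch_size, lr=cfg.train.lr,
        lr_final=cfg.train.lr_final,
    )
    norm_pairs = [s.preprocessed() for s in train_pairs]
    history = train(denoiser, norm_pairs, schedule, sampler, tconf, rngs["train"])
    return denoiser, history


def _write_histograms(path, val_pairs, sct_hu, lower_trunc: float) -> None:
    """Air-truncated HU histograms of the pooled validation slices."""
    from .metrics import hu_histogram

    pct = np.stack([s.pct for s in val_pairs])
    cbct = np.stack([s.cbct for s in val_pairs])
    rows = {}
    for label, imgs in (("pct", pct), ("cbct", cbct), ("sct", sct_hu)):
        counts, edges = hu_histogram(imgs, lower_trunc=lower_trunc)
        rows[label] = counts
    pd.DataFrame({"bin_left_hu": edges[:-1], **rows}).to_csv(path, index=False)


def run_experiment(cfg: ExperimentConfig, outdir) -> dict:
    """End-to-end run; returns summary objects and writes all artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rngs = _sub_rngs(cfg.seed)
    train_pairs, val_pairs = _generate_split(cfg, rngs["data"])
    schedule = cfg.schedule.make()
    denoiser, history = _train_model(cfg, train_pairs, schedule, rngs)
    per_tcon, scts = _evaluate_tcons(denoiser, schedule, val_pairs, cfg, rngs["sample"])

    summaries = []
    for t_con, df in per_tcon.items():
        np.savez_compressed(outdir / f"sct_tcon{t_con}.npz", sct_hu=scts[t_con])
        df.to_csv(outdir / f"metrics_per_slice_tcon{t_con}.csv", index=False)
        _write_histograms(outdir / f"histograms_tcon{t_con}.csv",
                          val_pairs, scts[t_con], cfg.eval.hist_lower_trunc)
        agg = aggregate_metrics(df)
        agg.columns = ["image"] + [f"{m}_{s}" for m, s in agg.columns[1:]]
        agg.insert(0, "t_con", t_con)
        summaries.append(agg)
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(outdir / "metrics_summary.csv", index=False)
    history.to_dataframe().to_csv(outdir / "loss_history.csv", index=False)
    cio.save_checkpoint(
        outdir / "checkpoint.npz", denoiser, schedule, {"config_hash": cfg.config_hash()}
    )
    (outdir / "config.yaml").write_text(cfg.to_yaml())
    (outdir / "manifest.json").write_text(
        json.dumps({"config_hash": cfg.config_hash(), "seed": cfg.seed})
    )
    return {
        "summary": summary,
        "per_tcon": per_tcon,
        "history": history,
        "denoiser": denoiser,
        "schedule": schedule,
        "outdir": outdir,
    }


def sweep_tcon(
    cfg: ExperimentConfig,
    t_cons: tuple[int, ...] = (1000, 900, 800, 700, 600, 500, 400),
    kinds: tuple[str, ...] = ("linear", "cosine", "sigmoid"),
    outdir=None,
) -> pd.DataFrame:
    """Schedule-by-t_con grid of masked sCT metrics (plus the CBCT
    baseline), one trained model per schedule kind."""
    rngs = _sub_rngs(cfg.seed)
    train_pairs, val_pairs = _generate_split(cfg, rngs["data"])
    rows = []
    for kind in kinds:
        schedule = cfg.schedule.make(kind)
        krngs = _sub_rngs(cfg.seed)  # identical init/train streams per kind
        denoiser, _ = _train_model(cfg, train_pairs, schedule, krngs)
        kcfg = cfg.model_copy(update={"sample": SampleBlock(t_con=tuple(t_cons))})
        per_tcon, _ = _evaluate_tcons(denoiser, schedule, val_pairs, kcfg, krngs["sample"])
        for t_con, df in per_tcon.items():
            for image in ("sct", "cbct"):
                sub = df[df["image"] == image]
                rows.append(
                    {
                        "schedule": kind,
                        "t_con": t_con,
                        "image": image,
                        "mae_hu": sub["mae_hu"].mean(),
                        "mae_hu_sd": sub["mae_hu"].std(),
                        "psnr_db": sub["psnr_db"].mean(),
                        "ncc": sub["ncc"].mean(),
                    }
                )
    grid = pd.DataFrame(rows)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        grid.to_csv(Path(outdir) / "tcon_sweep.csv", index=False)
    return grid


def sensitivity_sweep(
    cfg: ExperimentConfig, train_sizes: tuple[int, ...], outdir=None
) -> pd.DataFrame:
    """Metrics versus training-set size, evaluation pairs held fixed."""
    rngs = _sub_rngs(cfg.seed)
    train_pairs, val_pairs = _generate_split(cfg, rngs["data"])
    rows = []
    for size in train_sizes:
        if size > len(train_pairs):
            raise ValueError(f"train size {size} exceeds available {len(train_pairs)}")
        srngs = _sub_rngs(cfg.seed)
        schedule = cfg.schedule.make()
        denoiser, history = _train_model(cfg, train_pairs[:size], schedule, srngs)
        per_tcon, _ = _evaluate_tcons(denoiser, schedule, val_pairs, cfg, srngs["sample"])
        t_con = cfg.sample.t_con[0]
        sub = per_tcon[t_con][per_tcon[t_con]["image"] == "sct"]
        rows.append(
            {
                "train_size": size,
                "t_con": t_con,
                "mae_hu": sub["mae_hu"].mean(),
                "psnr_db": sub["psnr_db"].mean(),
                "ncc": sub["ncc"].mean(),
            }
        )
        if outdir is not None:
            Path(outdir).mkdir(parents=True, exist_ok=True)
            history.to_dataframe().to_csv(
                Path(outdir) / f"loss_history_size{size}.csv", index=False
            )
    table = pd.DataFrame(rows)
    if outdir is not None:
        table.to_csv(Path(outdir) / "sensitivity.csv", index=False)
    return table
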