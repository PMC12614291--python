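"""Volume, dataset and checkpoint I/O.

Volumes are NIfTI (via nibabel) with spacing carried in the affine;
generated datasets are NumPy archives with a JSON sidecar recording the
seeds and specs that produced them; checkpoints are single ``.npz``
archives holding the denoiser weights plus a JSON manifest (model config,
schedule parameters) sufficient to rebuild the sampler.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .nn.unet import Denoiser, DenoiserConfig
from .phantoms import FormatError, PairedSample
from .schedules import NoiseSchedule, make_schedule


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a NIfTI volume as a (Z, H, W) HU array plus (slice, row, col)
    spacing in mm."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # noqa: BLE001 - re-raise with filename context
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if len(zooms) != 3 or min(zooms) <= 0:
        raise FormatError(f"{path}: missing or invalid spacing metadata {zooms}")
    # nibabel axis order is (x, y, z); present as (slice, row, col)
    vol = np.transpose(data, (2, 1, 0))
    sx, sy, sz = (float(z) for z in zooms)
    return vol, (sz, sy, sx)


def write_volume(vol: np.ndarray, spacing: tuple[float, float, float], path) -> None:
    """Write a (Z, H, W) volume with (slice, row, col) spacing to NIfTI."""
    if len(spacing) != 3 or min(spacing) <= 0:
        raise FormatError(f"invalid spacing {spacing}")
    sz, sy, sx = spacing
    affine = np.diag([sx, sy, sz, 1.0])
    data = np.transpose(np.asarray(vol), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, affine), str(path))


def save_dataset(samples: list[PairedSample], path) -> None:
    """Archive paired samples as ``<path>.npz`` plus ``<path>.json``."""
    path = Path(path)
    arrays = {}
    sidecar = []
    for i, s in enumerate(samples):
        arrays[f"pct_{i}"] = s.pct
        arrays[f"cbct_{i}"] = s.cbct
        arrays[f"mask_{i}"] = s.fov_mask
        sidecar.append({"spacing": s.spacing, "unit_tag": s.unit_tag, "meta": s.meta})
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps({"n": len(samples), "samples": sidecar}))


def load_dataset(path) -> list[PairedSample]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as arc:
        samples = []
        for i, side in enumerate(meta["samples"]):
            samples.append(
                PairedSample(
                    pct=arc[f"pct_{i}"],
                    cbct=arc[f"cbct_{i}"],
                    fov_mask=arc[f"mask_{i}"].astype(bool),
                    spacing=tuple(side["spacing"]),
                    unit_tag=side["unit_tag"],
                    meta=side["meta"],
                )
            )
    return samples


def save_checkpoint(path, denoiser: Denoiser, schedule: NoiseSchedule, extra: dict | None = None) -> None:
    """Single-file checkpoint: weights + JSON manifest."""
    manifest = {
        "model": dataclasses.asdict(denoiser.cfg),
        "schedule": {
            "kind": schedule.kind,
            "T": schedule.T,
            "beta_min": schedule.beta_min,
            "beta_max": schedule.beta_max,
        },
        "extra": extra or {},
    }
    np.savez_compressed(
        path, __manifest__=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
        **denoiser.state_dict(),
    )


def load_checkpoint(path) -> tuple[Denoiser, NoiseSchedule, dict]:
    with np.load(path) as arc:
        manifest = json.loads(bytes(arc["__manifest__"]).decode())
        state = {k: arc[k] for k in arc.files if k != "__manifest__"}
    mcfg = manifest["model"]
    for key in ("channel_mults", "attention_levels"):
        if mcfg.get(key) is not None:
            mcfg[key] = tuple(mcfg[key])
    denoiser = Denoiser(DenoiserConfig(**mcfg), np.random.default_rng(0))
    denoiser.load_state_dict(state)
    schedule = make_schedule(**manifest["schedule"])
    return denoiser, schedule, manifest
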