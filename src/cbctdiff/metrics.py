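"""Masked image-quality metrics in HU space and diagnostic analyses.

Synthetic-CT quality is scored against the planning CT inside the circular
CBCT field-of-view mask, using three standard measures:

* MAE — mean absolute HU difference over the mask;
* PSNR — ``10 log10(R^2 / MSE)`` with a fixed reference range ``R = 4000``
  HU (the clipped intensity window), capped for identical images;
* NCC — zero-mean normalized cross-correlation, invariant to positive
  affine intensity rescaling.

Also provided: signed HU difference maps, air-truncated HU histograms, and
the latent-convergence analysis — how fast a pCT/CBCT pair noised with a
shared realisation approaches the same point of the diffusion latent
space (their distance contracts exactly as ``sqrt(alpha_bar_t)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diffusion import forward_diffuse
from .schedules import NoiseSchedule

#: Fixed PSNR reference range: width of the clipped HU window.
DATA_RANGE_HU = 4000.0

#: PSNR reported for a zero-MSE comparison.
PSNR_CAP_DB = 100.0


class MetricError(ValueError):
    """Invalid metric inputs."""


class UnitError(ValueError):
    """HU-space metric applied to normalized-unit data (or vice versa)."""


@dataclass(frozen=True)
class MetricsRecord:
    mae_hu: float
    psnr_db: float
    ncc: float
    n_pixels: int
    mask_id: str = "fov"

    def __post_init__(self):
        if self.mae_hu < 0 or not -1.0 <= self.ncc <= 1.0 or self.n_pixels <= 0:
            raise MetricError("metrics record violates invariants")


def _check(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None) -> np.ndarray | None:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise MetricError(f"shape mismatch: {a.shape} vs {b.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise MetricError(f"mask shape {mask.shape} != image shape {a.shape}")
        if not mask.any():
            raise MetricError("mask is empty")
    return mask


def masked_mae(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Mean |a - b| inside the mask."""
    mask = _check(a, b, mask)
    return float(np.abs(np.asarray(a)[mask] - np.asarray(b)[mask]).mean())


def masked_psnr(
    a: np.ndarray, b: np.ndarray, mask: np.ndarray, data_range: float = DATA_RANGE_HU
) -> float:
    """``10 log10(data_range^2 / MSE)`` inside the mask; capped when MSE=0."""
    mask = _check(a, b, mask)
    if data_range <= 0:
        raise MetricError("data_range must be > 0")
    mse = float(((np.asarray(a)[mask] - np.asarray(b)[mask]) ** 2).mean())
    if mse == 0.0:
        return PSNR_CAP_DB
    return float(min(10.0 * np.log10(data_range**2 / mse), PSNR_CAP_DB))


def masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation inside the mask."""
    mask = _check(a, b, mask)
    av = np.asarray(a, dtype=np.float64)[mask]
    bv = np.asarray(b, dtype=np.float64)[mask]
    ac = av - av.mean()
    bc = bv - bv.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        raise MetricError("NCC undefined for a constant image inside the mask")
    return float(np.clip(np.dot(ac, bc) / (na * nb), -1.0, 1.0))


def hu_difference_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signed difference ``a - b`` (unmasked, for visualization)."""
    _check(a, b, None)
    return np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)


def hu_histogram(
    img: np.ndarray, bin_width: float = 50.0, lower_trunc: float = -950.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of HU values over [lower_trunc, 3000], excluding pixels
    below the truncation limit (air would otherwise dominate).

    Returns ``(counts, bin_edges)``.
    """
    if bin_width <= 0:
        raise MetricError("bin_width must be > 0")
    upper = 3000.0
    edges = np.arange(lower_trunc, upper + bin_width, bin_width)
    v = np.asarray(img).ravel()
    counts, edges = np.histogram(v[v >= lower_trunc], bins=edges)
    return counts, edges


def latent_convergence_curve(
    x0: np.ndarray,
    y0: np.ndarray,
    schedule: NoiseSchedule,
    timesteps: Iterable[int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Cosine similarity and Euclidean distance between a pair noised with a
    SHARED realisation, per timestep.

    Because the same ``eps`` enters both one-shot diffusions,
    ``x_t - y_t = sqrt(alpha_bar_t) (x0 - y0)`` exactly: the distance decays
    as ``sqrt(alpha_bar_t)`` and the cosine similarity tends to 1 as the
    shared noise dominates.
    """
    x0, y0 = np.asarray(x0, dtype=np.float64), np.asarray(y0, dtype=np.float64)
    if x0.shape != y0.shape:
        raise MetricError("x0 and y0 must share shape")
    eps = rng.standard_normal(x0.shape)
    rows = []
    for t in timesteps:
        xt = forward_diffuse(x0, t, eps, schedule).ravel()
        yt = forward_diffuse(y0, t, eps, schedule).ravel()
        dist = float(np.linalg.norm(xt - yt))
        denom = np.linalg.norm(xt) * np.linalg.norm(yt)
        cos = float(np.dot(xt, yt) / denom) if denom else 1.0
        rows.append({"t": int(t), "cosine_similarity": cos, "euclidean_distance": dist})
    return pd.DataFrame(rows)


def export_difference_map_png(a: np.ndarray, b: np.ndarray, path,
                              vlim: float = 500.0) -> None:
    """Render the signed HU difference map to PNG (diverging colormap,
    symmetric limits in HU)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(hu_difference_map(a, b), cmap="RdBu_r", vmin=-vlim, vmax=vlim)
    fig.colorbar(im, ax=ax, label="HU difference")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def export_histogram_png(images: dict[str, np.ndarray], path,
                         bin_width: float = 50.0, lower_trunc: float = -950.0) -> None:
    """Overlay air-truncated HU histograms of labelled images to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, img in images.items():
        counts, edges = hu_histogram(img, bin_width, lower_trunc)
        ax.step(edges[:-1], counts, where="post", label=label)
    ax.set_xlabel("HU")
    ax.set_ylabel("pixels")
    ax.legend()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def evaluate_pairs(
    sct_set: Sequence[np.ndarray],
    pct_set: Sequence[np.ndarray],
    cbct_set: Sequence[np.ndarray],
    mask: np.ndarray,
    unit_tag: str = "HU",
    data_range: float = DATA_RANGE_HU,
    mask_id: str = "fov",
) -> pd.DataFrame:
    """Per-slice masked metrics for sCT-vs-pCT and CBCT-vs-pCT.

    All images must be in HU; pass ``unit_tag`` explicitly when arrays
    come from the normalized pipeline (a ``UnitError`` is raised so scores
    are never silently computed on the wrong scale).  Returns one row per
    slice; aggregate with :func:`aggregate_metrics`.
    """
    if unit_tag != "HU":
        raise UnitError(f"HU-space metrics require unit_tag='HU', got {unit_tag!r}")
    if not (len(sct_set) == len(pct_set) == len(cbct_set)):
        raise MetricError("sct/pct/cbct sets must have equal length")
    rows = []
    n_mask = int(np.asarray(mask, dtype=bool).sum())
    for i, (sct, pct, cbct) in enumerate(zip(sct_set, pct_set, cbct_set)):
        for label, img in (("sct", sct), ("cbct", cbct)):
            rows.append(
                {
                    "slice": i,
                    "image": label,
                    "mae_hu": masked_mae(img, pct, mask),
                    "psnr_db": masked_psnr(img, pct, mask, data_range),
                    "ncc": masked_ncc(img, pct, mask),
                    "n_pixels": n_mask,
                    "mask_id": mask_id,
                }
            )
    return pd.DataFrame(rows)


def aggregate_metrics(per_slice: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each metric per image type across slices."""
    return (
        per_slice.groupby("image")[["mae_hu", "psnr_db", "ncc"]]
        .agg(["mean", "std"])
        .reset_index()
    )
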