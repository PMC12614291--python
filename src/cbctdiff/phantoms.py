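"""Synthetic paired pCT/CBCT slice generation and preprocessing.

Real paired planning-CT / cone-beam-CT data cannot be redistributed, so
this module generates rigid paired slices with the statistical structure
the translation method assumes: a piecewise-constant "anatomy" (air
background, an elliptical soft-tissue body, embedded bone structures and
optional air cavities, each at a fixed HU level) serves as the planning CT,
and the matching CBCT is produced by applying the degradations cone-beam
acquisition is known for:

* a low-frequency radial HU bias field ("cupping"),
* additive streak lines through the object (metal/scatter streaks),
* additive Gaussian HU noise,
* a reduced circular field of view filled with air,
* a small rigid shift and a body-contour rescale emulating set-up error
  and weight change between the two acquisitions.

Degradations are applied in a fixed order (contour, shift, bias, streaks,
noise, FOV, clip) so that noise-free specs are exactly invertible, which
the tests exploit.  All randomness flows from the caller's generator.

The preprocessing chain matches the clinical pipeline: resample to a
common voxel size, center-crop, clip HU to [-1000, 3000] and rescale
affinely to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

HU_MIN = -1000.0
HU_MAX = 3000.0

UnitTag = Literal["HU", "normalized"]


class PhantomError(ValueError):
    """Invalid phantom/preprocessing parameters."""


class FormatError(ValueError):
    """Malformed volume metadata."""


@dataclass(frozen=True)
class AnatomySpec:
    """Material HU levels and geometry ranges for phantom slices."""

    air_hu: float = -1000.0
    soft_tissue_hu: float = 40.0
    bone_hu: float = 1000.0
    body_ry_frac: tuple[float, float] = (0.55, 0.75)  # of half-height
    body_rx_frac: tuple[float, float] = (0.60, 0.85)  # of half-width
    center_jitter_frac: float = 0.03
    n_bone_blobs: int = 2
    air_cavity_prob: float = 0.7


@dataclass(frozen=True)
class DegradationSpec:
    """CBCT degradation amplitudes; all units HU unless noted."""

    bias_amplitude: float = 60.0
    streak_count: int = 6
    streak_intensity: float = 120.0
    noise_sd: float = 20.0
    fov_radius_frac: float = 0.9
    shift_px: tuple[int, int] = (1, 1)
    contour_scale: float = 0.98  # relative body-outline rescale

    def __post_init__(self):
        if min(self.bias_amplitude, self.streak_intensity, self.noise_sd) < 0:
            raise PhantomError("degradation amplitudes must be >= 0")
        if not 0.0 < self.fov_radius_frac <= 1.0:
            raise PhantomError("fov_radius_frac must be in (0, 1]")


#: A spec that leaves the image untouched (identity degradation).
NULL_DEGRADATION = DegradationSpec(
    bias_amplitude=0.0, streak_count=0, streak_intensity=0.0, noise_sd=0.0,
    fov_radius_frac=1.0, shift_px=(0, 0), contour_scale=1.0,
)


@dataclass(frozen=True)
class PairedSample:
    """A registered (pCT, CBCT) slice pair with its CBCT FOV mask."""

    pct: np.ndarray
    cbct: np.ndarray
    fov_mask: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    unit_tag: UnitTag = "HU"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pct.shape != self.cbct.shape or self.pct.shape != self.fov_mask.shape:
            raise PhantomError("pct, cbct and fov_mask must share shape")

    def preprocessed(self) -> "PairedSample":
        """Normalized-unit copy of the pair."""
        if self.unit_tag == "normalized":
            return self
        return replace(
            self, pct=preprocess(self.pct), cbct=preprocess(self.cbct),
            unit_tag="normalized",
        )


# ---------------------------------------------------------------------------
# intensity maps
# ---------------------------------------------------------------------------

def preprocess(img: np.ndarray) -> np.ndarray:
    """HU -> normalized: clip to [-1000, 3000], then map affinely to [-1, 1]."""
    v = np.clip(np.asarray(img, dtype=np.float64), HU_MIN, HU_MAX)
    return (v - HU_MIN) / (HU_MAX - HU_MIN) * 2.0 - 1.0


def to_hu(img: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Normalized -> HU (exact inverse of :func:`preprocess` on its range)."""
    v = np.asarray(img, dtype=np.float64)
    if v.min() < -1.0 - atol or v.max() > 1.0 + atol:
        raise PhantomError(
            f"normalized input outside [-1, 1]: range [{v.min():.4g}, {v.max():.4g}]"
        )
    return (np.clip(v, -1.0, 1.0) + 1.0) / 2.0 * (HU_MAX - HU_MIN) + HU_MIN


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _center(shape: tuple[int, int]) -> tuple[float, float]:
    return ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)


def _radius_grid(shape: tuple[int, int]) -> np.ndarray:
    cy, cx = _center(shape)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)


def fov_mask(shape: tuple[int, int], radius_frac: float) -> np.ndarray:
    """Filled circle of radius ``radius_frac * min(shape)/2`` at the image
    center (row-major, origin top-left, center at ((H-1)/2, (W-1)/2))."""
    if not 0.0 < radius_frac <= 1.0:
        raise PhantomError("radius_frac must be in (0, 1]")
    r = radius_frac * min(shape) / 2.0
    return _radius_grid(shape) <= r


# ---------------------------------------------------------------------------
# phantom anatomy
# ---------------------------------------------------------------------------

def generate_phantom_ct(
    shape: tuple[int, int], spec: AnatomySpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant phantom slice and its body mask.

    Background air, an elliptical soft-tissue body, a posterior "spine"
    plus randomly placed bone blobs, and (usually) one anterior air
    cavity.  Geometry is randomized per draw; intensities take exactly the
    configured material levels.
    """
    h, w = shape
    if h < 32 or w < 32:
        raise PhantomError(f"shape must be at least 32x32, got {shape}")
    cy, cx = _center(shape)
    cy += rng.uniform(-1, 1) * spec.center_jitter_frac * h
    cx += rng.uniform(-1, 1) * spec.center_jitter_frac * w
    ry = rng.uniform(*spec.body_ry_frac) * h / 2.0
    rx = rng.uniform(*spec.body_rx_frac) * w / 2.0

    yy, xx = np.ogrid[:h, :w]
    body = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    img = np.full(shape, spec.air_hu)
    img[body] = spec.soft_tissue_hu

    def disk(c_y, c_x, r):
        return (yy - c_y) ** 2 + (xx - c_x) ** 2 <= r**2

    # posterior spine
    img[body & disk(cy + 0.55 * ry, cx, 0.16 * min(ry, rx))] = spec.bone_hu
    # random bone blobs inside the body
    for _ in range(spec.n_bone_blobs):
        ang = rng.uniform(0, 2 * np.pi)
        rho = rng.uniform(0.2, 0.6)
        by = cy + rho * ry * np.sin(ang)
        bx = cx + rho * rx * np.cos(ang)
        img[body & disk(by, bx, rng.uniform(0.08, 0.14) * min(ry, rx))] = spec.bone_hu
    # anterior air cavity
    if rng.random() < spec.air_cavity_prob:
        ay = cy - rng.uniform(0.2, 0.45) * ry
        ax = cx + rng.uniform(-0.25, 0.25) * rx
        img[body & disk(ay, ax, rng.uniform(0.06, 0.12) * min(ry, rx))] = spec.air_hu
    return img, body


# ---------------------------------------------------------------------------
# CBCT degradation
# ---------------------------------------------------------------------------

def cupping_field(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Radial HU bias: ``-amplitude * (1 - (r/rmax)^2)`` — strongest HU
    depression at the center, fading to zero at the inscribed-circle edge."""
    r = _radius_grid(shape)
    rmax = min(shape) / 2.0
    return -amplitude * np.clip(1.0 - (r / rmax) ** 2, 0.0, None)


def _streak_mask(shape, angle, offset, rng) -> np.ndarray:
    """1-px-wide line through the image at ``angle`` with perpendicular
    ``offset`` from the center."""
    h, w = shape
    cy, cx = _center(shape)
    d = np.array([np.sin(angle), np.cos(angle)])
    nvec = np.array([-d[1], d[0]])
    p = np.array([cy, cx]) + offset * nvec
    yy, xx = np.mgrid[:h, :w]
    dist = np.abs((yy - p[0]) * nvec[0] + (xx - p[1]) * nvec[1])
    return dist <= 0.5


def degrade_to_cbct(
    ct: np.ndarray, spec: DegradationSpec, rng: np.random.Generator
) -> np.ndarray:
    """Apply the CBCT degradation chain to a clean HU slice.

    Order: contour rescale -> rigid shift -> radial bias -> streaks ->
    noise -> circular FOV crop -> clip to [-1000, 3000].
    """
    img = np.asarray(ct, dtype=np.float64)
    shape = img.shape
    cy, cx = _center(shape)

    if spec.contour_scale != 1.0:
        s = spec.contour_scale
        mat = np.diag([1.0 / s, 1.0 / s])
        off = np.array([cy, cx]) - np.array([cy, cx]) / s
        img = ndimage.affine_transform(img, mat, offset=off, order=0, cval=HU_MIN)
    if spec.shift_px != (0, 0):
        img = ndimage.shift(img, spec.shift_px, order=0, cval=HU_MIN)
    if spec.bias_amplitude:
        img = img + cupping_field(shape, spec.bias_amplitude)
    for _ in range(spec.streak_count):
        angle = rng.uniform(0, np.pi)
        offset = rng.uniform(-0.3, 0.3) * min(shape) / 2.0
        sign = 1.0 if rng.random() < 0.5 else -1.0
        img = img + sign * spec.streak_intensity * _streak_mask(shape, angle, offset, rng)
    if spec.noise_sd:
        img = img + rng.normal(0.0, spec.noise_sd, shape)
    if spec.fov_radius_frac < 1.0:
        img = np.where(fov_mask(shape, spec.fov_radius_frac), img, HU_MIN)
    return np.clip(img, HU_MIN, HU_MAX)


def make_pair_dataset(
    n: int,
    anatomy_spec: AnatomySpec,
    degradation_spec: DegradationSpec,
    rng: np.random.Generator,
    shape: tuple[int, int] = (32, 32),
) -> list[PairedSample]:
    """Generate ``n`` independent registered pairs, each from its own child
    generator so pairs are reproducible and splittable by index."""
    if n < 1:
        raise PhantomError(f"n must be >= 1, got {n}")
    samples = []
    for i, child in enumerate(rng.spawn(n)):
        pct, _body = generate_phantom_ct(shape, anatomy_spec, child)
        cbct = degrade_to_cbct(pct, degradation_spec, child)
        samples.append(
            PairedSample(
                pct=pct,
                cbct=cbct,
                fov_mask=fov_mask(shape, degradation_spec.fov_radius_frac),
                meta={"index": i},
            )
        )
    return samples


# ---------------------------------------------------------------------------
# volume resampling
# ---------------------------------------------------------------------------

def resample_and_crop(
    volume: np.ndarray,
    spacing: tuple[float, float, float] | None,
    target_spacing: tuple[float, float, float] = (3.0, 1.0, 1.0),
    crop_size: int = 256,
) -> np.ndarray:
    """Linearly resample a (Z, H, W) HU volume to ``target_spacing`` (mm,
    (slice, row, col) order) and center-crop/pad each slice to
    ``crop_size`` square, padding with air."""
    if spacing is None or len(spacing) != 3 or min(spacing) <= 0:
        raise FormatError(f"invalid or missing spacing metadata: {spacing}")
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {vol.shape}")
    factors = tuple(s / t for s, t in zip(spacing, target_spacing))
    if factors != (1.0, 1.0, 1.0):
        vol = ndimage.zoom(vol, factors, order=1, mode="nearest", grid_mode=True)

    out = np.full((vol.shape[0], crop_size, crop_size), HU_MIN)
    for axis in (1, 2):
        size = vol.shape[axis]
        lo = max((size - crop_size) // 2, 0)
        vol = np.take(vol, range(lo, min(lo + crop_size, size)), axis=axis)
    oy = (crop_size - vol.shape[1]) // 2
    ox = (crop_size - vol.shape[2]) // 2
    out[:, oy : oy + vol.shape[1], ox : ox + vol.shape[2]] = vol
    return out
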