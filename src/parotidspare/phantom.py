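"""Synthetic head-and-neck phantoms: CPG + PTV structures and clinical-like dose.

The phantom emulates the geometry of a head-and-neck cohort: an ellipsoidal
contralateral parotid gland (CPG, ~20-40 cc) on the patient's right, a
spherical planning target volume (PTV) placed medially-caudally to reach a
requested CPG overlap fraction, and a dose grid carrying the prescription
inside the PTV with exponential distance falloff outside.  Defaults mirror
cohort-scale facts: 181.5 cc PTV, 13% overlap, 70 Gy prescription, 2.5 mm
isotropic dose grid, and ~3.3 cm CPG-PTV gap when overlap is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .rt_io import Grid3D, RoiContours

FALLOFF_LAMBDA_MM = 12.0     # exponential dose falloff length beyond the PTV
ZERO_OVERLAP_GAP_MM = 33.0   # CPG-PTV surface gap used when overlap target is 0
_N_POLY = 64                 # vertices per contour polygon

# unit direction from CPG center toward the PTV (medial, slightly
# posterior-caudal) - produces the caudal-medial high-dose gradient
_PTV_DIRECTION = np.array([1.0, 0.25, -0.5])
_PTV_DIRECTION /= np.linalg.norm(_PTV_DIRECTION)


class ParameterError(ValueError):
    """Phantom configuration cannot be realized."""


@dataclass(frozen=True)
class PhantomConfig:
    cpg_semiaxes: tuple[float, float, float] = (16.0, 19.0, 25.0)  # mm (x, y, z)
    cpg_center: tuple[float, float, float] = (-45.0, -5.0, 0.0)    # mm, patient right
    ptv_volume_target: float = 181.5          # cc (cohort median primary PTV)
    overlap_fraction_target: float = 0.13     # |CPG∩PTV| / |CPG| (cohort median)
    prescription: float = 70.0                # Gy
    grid_spacing: float = 2.5                 # mm isotropic
    noise_sd: float = 0.0                     # Gy, truncated-Gaussian dose noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction_target <= 0.35:
            raise ParameterError("overlap_fraction_target must lie in [0, 0.35]")
        if self.prescription <= 0:
            raise ParameterError("prescription must be positive")
        if self.grid_spacing <= 0 or min(self.cpg_semiaxes) <= 0:
            raise ParameterError("spacing and semiaxes must be positive")
        if self.ptv_volume_target <= 0:
            raise ParameterError("ptv_volume_target must be positive")


class Phantom(NamedTuple):
    config: PhantomConfig
    structures: list[RoiContours]
    clinical_dose: Grid3D


def _ptv_radius_mm(volume_cc: float) -> float:
    return (3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


def _ellipsoid_contours(
    name: str,
    center: np.ndarray,
    semiaxes: np.ndarray,
    z_levels: np.ndarray,
) -> RoiContours:
    """Per-slice elliptical polygons of an axis-aligned ellipsoid."""
    a, b, c = semiaxes
    theta = np.linspace(0.0, 2.0 * np.pi, _N_POLY, endpoint=False)
    slices = []
    for z in z_levels:
        t = (z - center[2]) / c
        if abs(t) >= 1.0:
            continue
        shrink = np.sqrt(1.0 - t * t)
        if a * shrink < 0.25 or b * shrink < 0.25:
            continue  # sub-voxel caps add nothing but degenerate polygons
        poly = np.column_stack(
            [center[0] + a * shrink * np.cos(theta), center[1] + b * shrink * np.sin(theta)]
        )
        slices.append((float(z), poly))
    return RoiContours(name=name, slices=slices)


def _ellipsoid_voxels(
    center: np.ndarray, semiaxes: np.ndarray, coords: tuple[np.ndarray, np.ndarray, np.ndarray]
) -> np.ndarray:
    xs, ys, zs = coords
    u = ((xs - center[0]) / semiaxes[0]) ** 2
    v = ((ys - center[1]) / semiaxes[1]) ** 2
    w = ((zs - center[2]) / semiaxes[2]) ** 2
    return (w[:, None, None] + v[None, :, None] + u[None, None, :]) <= 1.0


def _place_ptv(config: PhantomConfig) -> np.ndarray:
    """PTV center achieving the overlap target (bisection on separation)."""
    center = np.asarray(config.cpg_center, dtype=float)
    semi = np.asarray(config.cpg_semiaxes, dtype=float)
    r_ptv = _ptv_radius_mm(config.ptv_volume_target)
    # CPG half-extent along the placement direction (support function)
    extent = float(np.sqrt(np.sum((semi * _PTV_DIRECTION) ** 2)))

    if config.overlap_fraction_target == 0.0:
        return center + (extent + r_ptv + ZERO_OVERLAP_GAP_MM) * _PTV_DIRECTION

    # sample CPG interior at grid spacing; overlap fraction is relative to CPG
    h = config.grid_spacing
    axes = [np.arange(center[k] - semi[k], center[k] + semi[k] + h, h) for k in range(3)]
    xs, ys, zs = axes
    inside = _ellipsoid_voxels(center, semi, (xs, ys, zs))
    pts = np.stack(
        np.meshgrid(zs, ys, xs, indexing="ij"), axis=-1
    )[inside][:, ::-1]  # (N, 3) as (x, y, z)
    n_cpg = len(pts)

    def frac(d: float) -> float:
        c = center + d * _PTV_DIRECTION
        return float(np.sum(np.sum((pts - c) ** 2, axis=1) <= r_ptv**2)) / n_cpg

    lo, hi = 0.0, extent + r_ptv + 1.0
    if frac(lo) < config.overlap_fraction_target:
        raise ParameterError(
            "overlap target unreachable: PTV too small to overlap the CPG that much"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if frac(mid) >= config.overlap_fraction_target:
            lo = mid
        else:
            hi = mid
    return center + 0.5 * (lo + hi) * _PTV_DIRECTION


def make_phantom(config: PhantomConfig) -> Phantom:
    """Build structures (CPG, PTV) and a clinical-like dose grid.

    The PTV is placed by bisection so the voxel-measured overlap fraction
    matches the target within about +/-0.02; dose is ``prescription`` inside
    the PTV with ``exp(-d / 12 mm)`` falloff outside, plus optional Gaussian
    noise truncated at zero.  Fully deterministic for a fixed config.
    """
    center = np.asarray(config.cpg_center, dtype=float)
    semi = np.asarray(config.cpg_semiaxes, dtype=float)
    r_ptv = _ptv_radius_mm(config.ptv_volume_target)
    ptv_center = _place_ptv(config)

    h = config.grid_spacing
    margin = 15.0
    lo = np.minimum(center - semi, ptv_center - r_ptv) - margin
    hi = np.maximum(center + semi, ptv_center + r_ptv) + margin
    shape_xyz = np.ceil((hi - lo) / h).astype(int) + 1
    origin = tuple(lo)
    nz, ny, nx = int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0])
    grid = Grid3D(origin=origin, spacing=(h, h, h), values=np.zeros((nz, ny, nx)))
    xs, ys, zs = grid.axis_coords()

    cpg_roi = _ellipsoid_contours("CPG", center, semi, zs)
    ptv_roi = _ellipsoid_contours("PTV", ptv_center, np.full(3, r_ptv), zs)

    ptv_vox = _ellipsoid_voxels(ptv_center, np.full(3, r_ptv), (xs, ys, zs))
    dist_mm = ndimage.distance_transform_edt(~ptv_vox, sampling=(h, h, h))
    dose = config.prescription * np.exp(-dist_mm / FALLOFF_LAMBDA_MM)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        dose = np.maximum(dose + rng.normal(0.0, config.noise_sd, dose.shape), 0.0)
    return Phantom(config, [cpg_roi, ptv_roi], grid.like(dose))


def make_cohort(
    n: int,
    base_config: PhantomConfig = PhantomConfig(),
    seed: int = 0,
    jitter: float = 0.2,
    overlap_range: tuple[float, float] = (0.0, 0.33),
) -> list[Phantom]:
    """Generate a cohort of phantoms with jittered geometry.

    Semiaxes are scaled per-axis by U(1-jitter, 1+jitter) and the overlap
    fraction is sampled uniformly over ``overlap_range`` (default up to the
    cohort maximum of 33%).  ``jitter = 0`` reproduces the base config
    verbatim for every member.  Deterministic under ``seed``.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 phantoms")
    rng = np.random.default_rng(seed)
    phantoms = []
    for i in range(n):
        if jitter == 0.0:
            cfg = replace(base_config, seed=base_config.seed)
        else:
            scale = rng.uniform(1.0 - jitter, 1.0 + jitter, size=3)
            semi = tuple(float(s * f) for s, f in zip(base_config.cpg_semiaxes, scale))
            overlap = float(rng.uniform(*overlap_range))
            cfg = replace(
                base_config,
                cpg_semiaxes=semi,
                overlap_fraction_target=overlap,
                seed=int(rng.integers(2**31)),
            )
        phantoms.append(make_phantom(cfg))
    return phantoms
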