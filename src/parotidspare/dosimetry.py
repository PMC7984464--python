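"""Plan-evaluation dosimetry: subsegment means, DVH/V98, overlap, paired tests.

All quantities are evaluated on the dose grid itself; structures are
rasterized onto it first (no dose resampling onto structure-native grids).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rt_io import BinaryMask, Grid3D
from .subsegment import N_SUBSEGMENTS, LabelMap


@dataclass
class DvhCurve:
    """Cumulative dose-volume histogram: fraction of volume at or above dose."""

    dose_edges: np.ndarray       # Gy, ascending
    volume_fraction: np.ndarray  # same length; non-increasing, starts at 1


@dataclass
class PairedTestResult:
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p: float
    degenerate: bool = False  # zero variance of differences


def _check_geometry(dose: Grid3D, other) -> None:
    if dose.shape != other.shape or not np.allclose(dose.origin, other.origin):
        raise ValueError("dose and structure must share one grid geometry")


def subsegment_means(dose: Grid3D, ranked: LabelMap) -> np.ndarray:
    """Mean dose per rank S1..S18 (Gy); NaN marks ranks with no voxels."""
    _check_geometry(dose, ranked)
    means = np.full(N_SUBSEGMENTS, np.nan)
    for k in range(1, N_SUBSEGMENTS + 1):
        sel = ranked.labels == k
        if sel.any():
            means[k - 1] = dose.values[sel].mean()
    return means


def whole_mean(dose: Grid3D, mask: BinaryMask) -> float:
    """Mean dose over a mask (Gy)."""
    _check_geometry(dose, mask)
    if not mask.voxels.any():
        raise ValueError("empty mask")
    return float(dose.values[mask.voxels].mean())


def dmax(dose: Grid3D, mask: BinaryMask) -> float:
    _check_geometry(dose, mask)
    if not mask.voxels.any():
        raise ValueError("empty mask")
    return float(dose.values[mask.voxels].max())


def dvh(dose: Grid3D, mask: BinaryMask, bin_width: float = 0.1) -> DvhCurve:
    """Cumulative DVH on voxel values (differential histogram then cumsum)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    _check_geometry(dose, mask)
    vals = dose.values[mask.voxels]
    if vals.size == 0:
        raise ValueError("empty mask")
    top = float(vals.max())
    n_bins = int(np.ceil(top / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(vals, bins=edges)
    # fraction of voxels with dose >= lower edge of each bin
    frac = 1.0 - np.concatenate([[0.0], np.cumsum(hist)]) / vals.size
    return DvhCurve(dose_edges=edges, volume_fraction=frac)


def v_at(curve_or_dose, threshold: float, mask: BinaryMask | None = None) -> float:
    """Volume fraction receiving at least ``threshold`` Gy.

    Accepts either a :class:`DvhCurve` or a dose grid plus mask; the grid
    form counts voxels directly (``dose >= threshold``).
    """
    if isinstance(curve_or_dose, DvhCurve):
        curve = curve_or_dose
        if threshold <= curve.dose_edges[0]:
            return 1.0
        idx = np.searchsorted(curve.dose_edges, threshold, side="left")
        if idx >= len(curve.volume_fraction):
            return 0.0
        return float(curve.volume_fraction[idx])
    if mask is None:
        raise ValueError("mask required when passing a dose grid")
    vals = curve_or_dose.values[mask.voxels]
    if vals.size == 0:
        raise ValueError("empty mask")
    return float(np.mean(vals >= threshold))


def v98(dose: Grid3D, mask: BinaryMask, prescription: float) -> float:
    """Fraction of the structure receiving at least 98% of the prescription."""
    return v_at(dose, 0.98 * prescription, mask)


def overlap_fraction(cpg: BinaryMask, ptv_union: BinaryMask) -> float:
    """|CPG ∩ PTV| / |CPG|."""
    if cpg.shape != ptv_union.shape or not np.allclose(cpg.origin, ptv_union.origin):
        raise ValueError("masks must share one geometry")
    n_cpg = int(cpg.voxels.sum())
    if n_cpg == 0:
        raise ValueError("empty CPG mask")
    return float(np.sum(cpg.voxels & ptv_union.voxels)) / n_cpg


def min_distance(cpg: BinaryMask, ptv: BinaryMask) -> float:
    """Minimum voxel-center distance between two masks, in cm (0 if overlapping)."""
    if cpg.shape != ptv.shape or not np.allclose(cpg.origin, ptv.origin):
        raise ValueError("masks must share one geometry")
    if not cpg.voxels.any() or not ptv.voxels.any():
        raise ValueError("empty mask")
    if np.any(cpg.voxels & ptv.voxels):
        return 0.0
    from scipy.ndimage import distance_transform_edt

    dist_to_ptv = distance_transform_edt(~ptv.voxels, sampling=cpg.spacing[::-1])
    return float(dist_to_ptv[cpg.voxels].min()) / 10.0  # mm -> cm


def paired_t(a, b) -> PairedTestResult:
    """Two-sided paired t test on matched samples.

    Zero-variance differences are flagged degenerate, with t reported as 0
    when the mean difference is also 0 and +/-inf otherwise (p = NaN / 0 by
    the same convention as the t distribution limit).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_t needs two equal-length 1D samples, n >= 2")
    d = a - b
    n = len(d)
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if sd_diff == 0.0:
        t_val = 0.0 if mean_diff == 0.0 else float(np.sign(mean_diff)) * np.inf
        p_val = np.nan if mean_diff == 0.0 else 0.0
        return PairedTestResult(mean_diff, sd_diff, t_val, n - 1, p_val, degenerate=True)
    t_val = mean_diff / (sd_diff / np.sqrt(n))
    p_val = 2.0 * stats.t.sf(abs(t_val), df=n - 1)
    return PairedTestResult(mean_diff, sd_diff, float(t_val), n - 1, float(p_val))
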