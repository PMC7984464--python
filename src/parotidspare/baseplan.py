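"""Artificial base-plan synthesis and optimizer constraint bookkeeping.

A base plan (BP) is an artificial dose distribution loaded into the
optimizer as if it were already-delivered dose; combined with an upper
bound on the CPG it imposes a spatially varying constraint.  Construction
rules: dose is zero outside the CPG and in CPG-PTV overlap; dose is
uniform within each subsegment; the most important subsegment (S1)
receives D0 and subsegment Sk receives D0*I_k in the proportional mode.

Five standard variants: BP_10, BP_20, BP_30 (proportional, D0 = 10/20/30
Gy over all 18 ranks), BP_20,5 (proportional D0 = 20 Gy restricted to
S1-S5), and BP_top5 (uniform 50 Gy on S1-S5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .rt_io import BinaryMask, Grid3D
from .subsegment import N_SUBSEGMENTS, LabelMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BasePlanSpec:
    """Recipe for one artificial base-plan variant."""

    name: str
    mode: str                        # "proportional" | "uniform_subset"
    d0: float | None = None          # Gy, proportional mode
    included_ranks: frozenset[int] = frozenset(range(1, N_SUBSEGMENTS + 1))
    subset_dose: float | None = None  # Gy, uniform_subset mode

    def __post_init__(self) -> None:
        if self.mode not in ("proportional", "uniform_subset"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "proportional" and (self.d0 is None or self.d0 <= 0):
            raise ValueError("proportional mode requires d0 > 0")
        if self.mode == "uniform_subset" and (
            self.subset_dose is None or self.subset_dose <= 0
        ):
            raise ValueError("uniform_subset mode requires subset_dose > 0")
        if not self.included_ranks:
            raise ValueError("included_ranks must be non-empty")


@dataclass(frozen=True)
class ConstraintSet:
    """CPG constraints to accompany a base plan during optimization."""

    cpg_dmax_bound: float          # Gy: max(BP) + dmax_margin
    cpg_mean_bound_shifted: float  # Gy: clinical mean bound + mean(BP | CPG)
    dmax_margin: float             # Gy in [0, 15]


def make_variant_suite(
    d0_linear: tuple[float, float, float] = (10.0, 20.0, 30.0),
    subset_d0: float = 20.0,
    subset_dose: float = 50.0,
) -> list[BasePlanSpec]:
    """The five standard base-plan variants."""
    top5 = frozenset(range(1, 6))
    specs = [
        BasePlanSpec(name=f"BP_{d0:g}", mode="proportional", d0=d0)
        for d0 in d0_linear
    ]
    specs.append(
        BasePlanSpec(
            name=f"BP_{subset_d0:g},5",
            mode="proportional",
            d0=subset_d0,
            included_ranks=top5,
        )
    )
    specs.append(
        BasePlanSpec(
            name="BP_top5",
            mode="uniform_subset",
            subset_dose=subset_dose,
            included_ranks=top5,
        )
    )
    return specs


def build_base_plan(
    ranked: LabelMap,
    ptv_mask: BinaryMask,
    spec: BasePlanSpec,
    scaling: np.ndarray,
) -> Grid3D:
    """Synthesize one artificial base-plan dose grid.

    ``scaling`` are the importance factors I_1..I_18 (I_1 = 1).  The result
    is zero outside the CPG and wherever the CPG overlaps the PTV union,
    and exactly uniform within each remaining subsegment region.
    """
    if ranked.shape != ptv_mask.shape or not np.allclose(
        ranked.origin, ptv_mask.origin
    ):
        raise ValueError("ranked label map and PTV mask must share one geometry")
    scaling = np.asarray(scaling, dtype=float)
    if scaling.shape != (N_SUBSEGMENTS,):
        raise ValueError("need 18 scaling factors")

    per_rank = np.zeros(N_SUBSEGMENTS + 1)
    if spec.mode == "proportional":
        for k in spec.included_ranks:
            per_rank[k] = spec.d0 * scaling[k - 1]
    else:
        for k in spec.included_ranks:
            per_rank[k] = spec.subset_dose

    values = per_rank[ranked.labels]
    values[ptv_mask.voxels] = 0.0
    if not values.any() and (ranked.labels > 0).any():
        logger.warning(
            "base plan %s is identically zero (CPG fully overlapped or zero scaling)",
            spec.name,
        )
    return Grid3D(ranked.origin, ranked.spacing, values)


def constraint_set(
    bp: Grid3D,
    cpg_mask: BinaryMask,
    clinical_mean_bound: float,
    dmax_margin: float,
) -> ConstraintSet:
    """Constraint values for a plan optimized on top of a base plan.

    The upper bound on the CPG is the base-plan maximum plus a margin of
    0-15 Gy; the whole-mean bound is shifted up by the base plan's mean
    dose inside the CPG, since that mean is absorbed into the gland mean
    during optimization.
    """
    if not 0.0 <= dmax_margin <= 15.0:
        raise ValueError("dmax_margin must lie in [0, 15] Gy")
    if not bp.same_geometry(cpg_mask):
        raise ValueError("base plan and CPG mask must share one geometry")
    if not cpg_mask.voxels.any():
        raise ValueError("empty CPG mask")
    bp_max = float(bp.values.max())
    bp_mean_cpg = float(bp.values[cpg_mask.voxels].mean())
    return ConstraintSet(
        cpg_dmax_bound=bp_max + dmax_margin,
        cpg_mean_bound_shifted=clinical_mean_bound + bp_mean_cpg,
        dmax_margin=dmax_margin,
    )
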