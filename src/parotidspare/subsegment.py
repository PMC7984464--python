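"""Equal-volume subsegmentation of the contralateral parotid gland (CPG).

The gland mask is partitioned into 18 equal-volume cells by nested
voxel-count quantile splits — cranio-caudal into 3 slabs, each slab
antero-posterior into 3, each cell medial-lateral into 2 — and the cells
are then relabeled S1..S18 in order of decreasing relative importance via
a configurable octant map.  The importance of the top-ranked subsegment
(caudal-anterior) is 3.85 times the expectation for a homogeneous gland;
scaling factors are normalized so I1 = 1.

The full 18-value importance table is configuration, not code: the
default shipped in ``data/importance_18.json`` is a documented placeholder
(geometric decay) to be replaced with published population values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import ndimage

from .rt_io import BinaryMask

logger = logging.getLogger(__name__)

N_SUBSEGMENTS = 18
CC_THIRDS = ("caudal", "mid", "cranial")      # +z = cranial
AP_THIRDS = ("anterior", "mid", "posterior")  # +y = posterior
ML_HALVES = ("medial", "lateral")


class ConfigError(ValueError):
    """An importance table or octant map violates its invariants."""


@dataclass
class LabelMap:
    """Integer subsegment labels on a grid geometry (0 = background)."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")

    @property
    def shape(self):
        return self.labels.shape

    def rank_mask(self, rank: int) -> np.ndarray:
        return self.labels == rank

    def counts(self) -> np.ndarray:
        """Voxel count per label 1..18."""
        return np.bincount(self.labels.ravel(), minlength=N_SUBSEGMENTS + 1)[1:]


@dataclass
class ImportanceTable:
    """Per-rank relative importance and the rank <-> octant assignment.

    ``importance[k-1]`` is the raw importance of rank k (non-increasing);
    ``octant_map`` maps ``(cc_third, ap_third, ml_half)`` names to ranks and
    must be a bijection over the 18 cells with the caudal-anterior-medial
    cell at rank 1.
    """

    importance: np.ndarray
    octant_map: dict[tuple[str, str, str], int]

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if self.importance.shape != (N_SUBSEGMENTS,):
            raise ConfigError("importance table needs exactly 18 values")
        if np.any(self.importance < 0):
            raise ConfigError("importance values must be non-negative")
        if np.any(np.diff(self.importance) > 1e-12):
            raise ConfigError("importance must be non-increasing in rank")
        cells = {
            (cc, ap, ml) for cc in CC_THIRDS for ap in AP_THIRDS for ml in ML_HALVES
        }
        if set(self.octant_map) != cells or sorted(self.octant_map.values()) != list(
            range(1, N_SUBSEGMENTS + 1)
        ):
            raise ConfigError("octant_map must be a bijection cells <-> ranks 1..18")


def load_importance_table(path: str | Path | None = None) -> ImportanceTable:
    """Load an importance table from JSON (package default if no path).

    Format: ``[{"rank": k, "octant": {"cc_third": ..., "ap_third": ...,
    "ml_half": ...}, "importance": v}, ...]`` with 18 entries.
    """
    if path is None:
        text = (
            resources.files("parotidspare.data")
            .joinpath("importance_18.json")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    entries = json.loads(text)
    if isinstance(entries, dict):
        entries = entries["subsegments"]
    importance = np.zeros(N_SUBSEGMENTS)
    octant_map: dict[tuple[str, str, str], int] = {}
    for e in entries:
        rank = int(e["rank"])
        if not 1 <= rank <= N_SUBSEGMENTS:
            raise ConfigError(f"rank {rank} outside 1..18")
        importance[rank - 1] = float(e["importance"])
        o = e["octant"]
        octant_map[(o["cc_third"], o["ap_third"], o["ml_half"])] = rank
    return ImportanceTable(importance=importance, octant_map=octant_map)


def _ordered_split(order: np.ndarray, n_parts: int) -> list[np.ndarray]:
    """Split an ordered index array into n_parts proportionally-rounded runs."""
    n = len(order)
    bounds = [int(np.floor(k * n / n_parts + 0.5)) for k in range(n_parts + 1)]
    return [order[bounds[k] : bounds[k + 1]] for k in range(n_parts)]


def partition_equal_volume(gland: BinaryMask) -> LabelMap:
    """Partition a gland mask into 18 equal-voxel-count spatial cells.

    Cells are labeled 1..18 in geometric order (cranio-caudal third, then
    antero-posterior third, then medial-lateral half along +x); ranking by
    importance is a separate step (:func:`assign_ranks`).  Boundary voxels
    at each quantile go to the lower cell, with ties broken by sorting on
    the split axis then the remaining axes in (z, y, x) order.
    """
    vox = np.argwhere(gland.voxels)  # (N, 3) as (iz, iy, ix)
    n = len(vox)
    if n < N_SUBSEGMENTS:
        raise ValueError(f"gland has {n} voxels; cannot form 18 subsegments")
    _, n_components = ndimage.label(gland.voxels)
    if n_components > 1:
        logger.warning(
            "gland mask has %d connected components; partitioning anyway",
            n_components,
        )

    iz, iy, ix = vox[:, 0], vox[:, 1], vox[:, 2]
    labels = np.zeros(gland.shape, dtype=np.int16)
    # lexsort: last key is primary
    z_order = np.lexsort((ix, iy, iz))
    for cc, slab in enumerate(_ordered_split(z_order, 3)):
        y_order = slab[np.lexsort((ix[slab], iz[slab], iy[slab]))]
        for ap, cell in enumerate(_ordered_split(y_order, 3)):
            x_order = cell[np.lexsort((iy[cell], iz[cell], ix[cell]))]
            for ml, half in enumerate(_ordered_split(x_order, 2)):
                labels[iz[half], iy[half], ix[half]] = cc * 6 + ap * 2 + ml + 1
    return LabelMap(gland.origin, gland.spacing, labels)


def _cell_octant(cell_label: int, laterality: str) -> tuple[str, str, str]:
    """Anatomical octant of a geometric cell label for a given laterality.

    Geometric x runs right -> left; for a right-sided gland the high-x half
    is medial (toward midline), for a left-sided gland it is lateral.
    """
    c = cell_label - 1
    cc, ap, ml_x = c // 6, (c % 6) // 2, c % 2
    if laterality == "right":
        ml = "medial" if ml_x == 1 else "lateral"
    elif laterality == "left":
        ml = "medial" if ml_x == 0 else "lateral"
    else:
        raise ValueError("laterality must be 'left' or 'right'")
    return (CC_THIRDS[cc], AP_THIRDS[ap], ml)


def assign_ranks(
    cells: LabelMap, table: ImportanceTable, laterality: str = "right"
) -> LabelMap:
    """Relabel geometric cells to importance ranks S1..S18.

    The medial-lateral axis is interpreted per laterality so that mirrored
    left/right glands receive identical anatomical ranks; the
    caudal-anterior(-medial) cell maps to rank 1 with the default table.
    """
    present = np.unique(cells.labels)
    present = present[present > 0]
    if len(present) != N_SUBSEGMENTS:
        raise ValueError(
            f"expected 18 non-empty cells, found {len(present)}"
        )
    lut = np.zeros(N_SUBSEGMENTS + 1, dtype=np.int16)
    for cell_label in range(1, N_SUBSEGMENTS + 1):
        octant = _cell_octant(cell_label, laterality)
        lut[cell_label] = table.octant_map[octant]
    return LabelMap(cells.origin, cells.spacing, lut[cells.labels])


def scaling_factors(table: ImportanceTable) -> np.ndarray:
    """Importance scaling factors I_1..I_18 normalized so I_1 = 1."""
    if table.importance[0] <= 0:
        raise ConfigError("rank-1 importance must be positive")
    return table.importance / table.importance[0]
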