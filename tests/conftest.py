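import dataclasses

import numpy as np
import pytest

import parotidspare as ps


@pytest.fixture(scope="session")
def importance_table():
    return ps.load_importance_table()


@pytest.fixture(scope="session")
def hill_params():
    return ps.load_hill_params()


@pytest.fixture(scope="session")
def phantom_default():
    """Default phantom: 13% CPG-PTV overlap, 70 Gy, 2.5 mm grid."""
    return ps.make_phantom(ps.PhantomConfig())


@pytest.fixture(scope="session")
def phantom_no_overlap():
    cfg = dataclasses.replace(ps.PhantomConfig(), overlap_fraction_target=0.0)
    return ps.make_phantom(cfg)


def _masks(phantom):
    grid = phantom.clinical_dose
    rois = {r.name: r for r in phantom.structures}
    return ps.rasterize(rois["CPG"], grid), ps.rasterize(rois["PTV"], grid)


@pytest.fixture(scope="session")
def masks_default(phantom_default):
    return _masks(phantom_default)


@pytest.fixture(scope="session")
def masks_no_overlap(phantom_no_overlap):
    return _masks(phantom_no_overlap)


@pytest.fixture(scope="session")
def ranked_no_overlap(masks_no_overlap, importance_table):
    cpg, _ = masks_no_overlap
    cells = ps.partition_equal_volume(cpg)
    return ps.assign_ranks(cells, importance_table, laterality="right")


@pytest.fixture(scope="session")
def ranked_default(masks_default, importance_table):
    cpg, _ = masks_default
    cells = ps.partition_equal_volume(cpg)
    return ps.assign_ranks(cells, importance_table, laterality="right")


def make_box_mask(nx=30, ny=30, nz=20, spacing=1.0):
    """Rectangular 18,000-voxel gland on a padded grid (exact 18-way split)."""
    shape = (nz + 4, ny + 4, nx + 4)
    vox = np.zeros(shape, dtype=bool)
    vox[2 : 2 + nz, 2 : 2 + ny, 2 : 2 + nx] = True
    return ps.BinaryMask((0.0, 0.0, 0.0), (spacing,) * 3, vox)


def make_ellipsoid_mask(semiaxes, spacing=1.25, center=(0.0, 0.0, 0.0)):
    a, b, c = semiaxes
    xs = np.arange(-a - 2 * spacing, a + 2 * spacing, spacing) + center[0]
    ys = np.arange(-b - 2 * spacing, b + 2 * spacing, spacing) + center[1]
    zs = np.arange(-c - 2 * spacing, c + 2 * spacing, spacing) + center[2]
    u = ((xs - center[0]) / a) ** 2
    v = ((ys - center[1]) / b) ** 2
    w = ((zs - center[2]) / c) ** 2
    vox = (w[:, None, None] + v[None, :, None] + u[None, None, :]) <= 1.0
    origin = (float(xs[0]), float(ys[0]), float(zs[0]))
    return ps.BinaryMask(origin, (spacing,) * 3, vox)
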