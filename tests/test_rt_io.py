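"""Grid primitives and DICOM RT round-trips."""

import logging

import numpy as np
import pydicom
import pytest

import parotidspare as ps
from parotidspare.rt_io import FormatError


def random_grid(rng, shape=(6, 5, 4), spacing=(2.0, 2.5, 3.0)):
    return ps.Grid3D(
        origin=(-10.0, -5.0, 0.0),
        spacing=spacing,
        values=rng.uniform(0.0, 75.0, size=shape),
    )


class TestRtDose:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_round_trip_within_quantization(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        grid = random_grid(rng)
        ps.write_rtdose(grid, tmp_path / "d.dcm")
        back = ps.read_rtdose(tmp_path / "d.dcm")
        assert back.values.shape == grid.values.shape
        assert np.allclose(back.origin, grid.origin, atol=1e-6)
        assert np.allclose(back.spacing, grid.spacing, atol=1e-6)
        # 32-bit storage: error far below the generic 2^(bits-1) bound
        bound = grid.values.max() / 2**31
        assert np.abs(back.values - grid.values).max() <= bound

    def test_constant_grid_round_trip(self, tmp_path):
        grid = ps.Grid3D((0, 0, 0), (1, 1, 1), np.full((3, 3, 3), 2.0))
        ps.write_rtdose(grid, tmp_path / "d.dcm")
        back = ps.read_rtdose(tmp_path / "d.dcm")
        assert np.allclose(back.values, 2.0, atol=2.0 / 2**31)

    def test_zero_grid_reads_back_identically_zero(self, tmp_path):
        grid = ps.Grid3D((0, 0, 0), (1, 1, 1), np.zeros((3, 4, 5)))
        ps.write_rtdose(grid, tmp_path / "z.dcm")
        assert np.all(ps.read_rtdose(tmp_path / "z.dcm").values == 0.0)

    def test_dose_scaling_is_applied(self, tmp_path):
        grid = ps.Grid3D((0, 0, 0), (1, 1, 1), np.ones((2, 2, 2)))
        path = ps.write_rtdose(grid, tmp_path / "d.dcm")
        ds = pydicom.dcmread(path)
        ds.DoseGridScaling = "0.001"
        ds.PixelData = np.full(8, 3000, dtype="<u4").tobytes()
        ds.save_as(path, enforce_file_format=True)
        assert np.allclose(ps.read_rtdose(path).values, 3.0)

    def test_negative_dose_rejected(self, tmp_path):
        grid = ps.Grid3D((0, 0, 0), (1, 1, 1), np.zeros((2, 2, 2)))
        grid.values[0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            ps.write_rtdose(grid, tmp_path / "bad.dcm")

    def test_non_uniform_frame_offsets_rejected(self, tmp_path):
        grid = ps.Grid3D((0, 0, 0), (1, 1, 1), np.ones((3, 2, 2)))
        path = ps.write_rtdose(grid, tmp_path / "d.dcm")
        ds = pydicom.dcmread(path)
        ds.GridFrameOffsetVector = ["0.0", "1.0", "3.0"]
        ds.save_as(path, enforce_file_format=True)
        with pytest.raises(FormatError, match="non-uniform"):
            ps.read_rtdose(path)


class TestRtStruct:
    def test_square_contour_round_trip(self, tmp_path):
        square = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]])
        roi = ps.RoiContours("BOX", [(0.0, square)])
        ps.write_rtstruct([roi], tmp_path / "s.dcm")
        (back,) = ps.read_rtstruct(tmp_path / "s.dcm")
        assert back.name == "BOX"
        assert len(back.slices) == 1
        z, poly = back.slices[0]
        assert z == 0.0 and poly.shape == (4, 2)
        assert np.allclose(poly, square)

    def test_empty_roi_skipped_with_warning(self, tmp_path, caplog):
        square = np.array([[0.0, 0.0], [5.0, 0.0], [5.0, 5.0], [0.0, 5.0]])
        ps.write_rtstruct(
            [ps.RoiContours("FULL", [(0.0, square)]), ps.RoiContours("EMPTY", [])],
            tmp_path / "s.dcm",
        )
        with caplog.at_level(logging.WARNING):
            rois = ps.read_rtstruct(tmp_path / "s.dcm")
        assert [r.name for r in rois] == ["FULL"]
        assert any("EMPTY" in rec.message for rec in caplog.records)

    def test_phantom_structures_round_trip_preserves_masks(
        self, tmp_path, phantom_default, masks_default
    ):
        grid = phantom_default.clinical_dose
        ps.write_rtstruct(phantom_default.structures, tmp_path / "s.dcm")
        rois = {r.name: r for r in ps.read_rtstruct(tmp_path / "s.dcm")}
        assert set(rois) == {"CPG", "PTV"}
        cpg, _ = masks_default
        assert np.array_equal(ps.rasterize(rois["CPG"], grid).voxels, cpg.voxels)


class TestRasterize:
    def test_square_exact_containment(self):
        # 10x10 mm square centered on a 1 mm grid: 100 centers strictly inside
        square = np.array([[-5.0, -5.0], [5.0, -5.0], [5.0, 5.0], [-5.0, 5.0]])
        grid = ps.Grid3D((-9.5, -9.5, 0.0), (1.0, 1.0, 1.0), np.zeros((1, 20, 20)))
        mask = ps.rasterize(ps.RoiContours("SQ", [(0.0, square)]), grid)
        assert mask.voxels.sum() == 100

    def test_circle_area_converges(self):
        r = 20.0
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        circle = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        grid = ps.Grid3D((-24.75, -24.75, 0.0), (0.5, 0.5, 0.5), np.zeros((1, 100, 100)))
        mask = ps.rasterize(ps.RoiContours("C", [(0.0, circle)]), grid)
        area = mask.voxels.sum() * 0.25
        assert abs(area - np.pi * r**2) / (np.pi * r**2) < 0.01

    def test_resolution_refinement_improves_area(self):
        r = 15.0
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        circle = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        errs = []
        for h, n in ((2.0, 20), (0.5, 80)):
            grid = ps.Grid3D(
                (-(n / 2 - 0.5) * h, -(n / 2 - 0.5) * h, 0.0),
                (h, h, h),
                np.zeros((1, n, n)),
            )
            mask = ps.rasterize(ps.RoiContours("C", [(0.0, circle)]), grid)
            errs.append(abs(mask.voxels.sum() * h * h - np.pi * r**2))
        assert errs[1] < errs[0]

    def test_contour_beyond_slices_gives_empty_mask(self, caplog):
        square = np.array([[0.0, 0.0], [5.0, 0.0], [5.0, 5.0], [0.0, 5.0]])
        # contour plane more than dz/2 beyond every grid slice
        grid = ps.Grid3D((0.0, 0.0, 0.0), (1.0, 1.0, 4.0), np.zeros((2, 10, 10)))
        with caplog.at_level(logging.WARNING):
            mask = ps.rasterize(ps.RoiContours("GAP", [(20.0, square)]), grid)
        assert not mask.voxels.any()
        assert any("GAP" in rec.message for rec in caplog.records)

    def test_phantom_cpg_volume_close_to_analytic(self):
        cfg = ps.PhantomConfig(grid_spacing=1.0)
        ph = ps.make_phantom(cfg)
        rois = {r.name: r for r in ph.structures}
        mask = ps.rasterize(rois["CPG"], ph.clinical_dose)
        a, b, c = cfg.cpg_semiaxes
        analytic = 4.0 / 3.0 * np.pi * a * b * c / 1000.0
        assert abs(mask.volume_cc - analytic) / analytic < 0.02


class TestResample:
    def test_constant_preserved(self):
        src = ps.Grid3D((0, 0, 0), (2, 2, 2), np.full((8, 8, 8), 5.0))
        dst = ps.Grid3D((2, 2, 2), (1.5, 1.5, 1.5), np.zeros((5, 5, 5)))
        out = ps.resample(src, dst)
        assert np.allclose(out.values, 5.0)

    def test_identity_geometry_bitwise_equal(self):
        rng = np.random.default_rng(7)
        src = random_grid(rng)
        out = ps.resample(src, src)
        assert np.array_equal(out.values, src.values)

    def test_linear_ramp_reproduced_exactly(self):
        xs = np.arange(10) * 2.0
        src = ps.Grid3D(
            (0, 0, 0), (2, 2, 2), np.broadcast_to(3.0 * xs, (6, 6, 10)).copy()
        )
        dst = ps.Grid3D((1.0, 1.0, 1.0), (1.0, 2.0, 2.0), np.zeros((4, 4, 8)))
        out = ps.resample(src, dst)
        expected = 3.0 * (1.0 + np.arange(8) * 1.0)
        assert np.allclose(out.values, expected[None, None, :], atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_interior_values_stay_within_source_range(self, seed):
        rng = np.random.default_rng(seed)
        src = random_grid(rng, shape=(7, 7, 7), spacing=(2.0, 2.0, 2.0))
        dst = ps.Grid3D((-9.0, -4.0, 1.0), (1.1, 1.3, 1.7), np.zeros((6, 6, 6)))
        out = ps.resample(src, dst)
        assert out.values.min() >= src.values.min() - 1e-12
        assert out.values.max() <= src.values.max() + 1e-12
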