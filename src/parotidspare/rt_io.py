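"""DICOM RT I/O and the grid / mask / rasterization primitives.

Conventions
-----------
All coordinates are patient millimetres, head-first supine, axis-aligned
(identity direction cosines): +x toward the patient's left, +y posterior,
+z superior (cranial).  Dose arrays are indexed ``values[iz, iy, ix]``;
``origin`` and ``spacing`` are ``(x, y, z)`` triples referring to voxel
*centers*.  Oblique grids are rejected.

RT-DOSE is stored as 32-bit unsigned integers with a per-file
``DoseGridScaling`` chosen so the grid maximum uses the full integer
range, which bounds the round-trip quantization error by
``max(dose) / 2**32``.
"""

from __future__ import annotations

import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy.interpolate import RegularGridInterpolator

logger = logging.getLogger(__name__)

_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_IDENTITY_IOP = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


class FormatError(ValueError):
    """A DICOM file does not conform to the subset this package supports."""


@dataclass
class Grid3D:
    """Axis-aligned 3D scalar field (dose in Gy, or unitless).

    Parameters
    ----------
    origin : (x, y, z) mm of the center of voxel ``[0, 0, 0]``.
    spacing : (dx, dy, dz) mm, strictly positive.
    values : float array of shape ``(nz, ny, nx)``.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array (nz, ny, nx)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # (nz, ny, nx)

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates ``(xs, ys, zs)`` along each axis."""
        nz, ny, nx = self.values.shape
        ox, oy, oz = self.origin
        dx, dy, dz = self.spacing
        return (
            ox + dx * np.arange(nx),
            oy + dy * np.arange(ny),
            oz + dz * np.arange(nz),
        )

    def same_geometry(self, other: "Grid3D | BinaryMask") -> bool:
        return (
            self.values.shape == _shape_of(other)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.spacing, other.spacing)
        )

    def like(self, values: np.ndarray) -> "Grid3D":
        """New grid with this geometry and the given values."""
        return Grid3D(self.origin, self.spacing, values)

    @property
    def voxel_volume_cc(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0


@dataclass
class BinaryMask:
    """Boolean voxel assignment on a :class:`Grid3D` geometry."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D boolean array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_cc(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    @property
    def volume_cc(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume_cc

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return Grid3D(self.origin, self.spacing, np.zeros(self.shape)).axis_coords()


@dataclass
class RoiContours:
    """Planar closed contours of one ROI: ``(z, polygon)`` pairs in mm."""

    name: str
    slices: list[tuple[float, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for z, poly in self.slices:
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(
                    f"ROI {self.name!r}: polygons need >=3 (x, y) vertices"
                )
            # store implicitly closed (drop a duplicated final vertex)
            if np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]
            cleaned.append((float(z), poly))
        cleaned.sort(key=lambda item: item[0])
        self.slices = cleaned


def _shape_of(g) -> tuple[int, int, int]:
    return g.values.shape if hasattr(g, "values") else g.voxels.shape


# ---------------------------------------------------------------------------
# DICOM RT-STRUCT
# ---------------------------------------------------------------------------

def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _base_dataset(sop_class: str, modality: str) -> FileDataset:
    sop_instance = generate_uid()
    ds = FileDataset(
        None, {}, file_meta=_file_meta(sop_class, sop_instance), preamble=b"\0" * 128
    )
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_instance
    ds.Modality = modality
    ds.PatientName = "PHANTOM^SYNTHETIC"
    ds.PatientID = "PHANTOM"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    ds.StudyDate = ""
    ds.StudyTime = ""
    return ds


def write_rtstruct(rois: Iterable[RoiContours], path: str | Path) -> Path:
    """Write ROIs to a minimal DICOM RT-STRUCT file."""
    path = Path(path)
    ds = _base_dataset(_RTSTRUCT_SOP, "RTSTRUCT")
    ds.StructureSetLabel = "SYNTHETIC"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    ds.RTROIObservationsSequence = []
    for number, roi in enumerate(rois, start=1):
        sroi = Dataset()
        sroi.ROINumber = number
        sroi.ROIName = roi.name
        sroi.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        sroi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(sroi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for z, poly in roi.slices:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = poly.shape[0]
            data = np.column_stack([poly, np.full(poly.shape[0], z)])
            c.ContourData = [f"{v:.6f}" for v in data.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)
    return path


def read_rtstruct(path: str | Path) -> list[RoiContours]:
    """Read every contoured ROI from an RT-STRUCT file.

    ROIs without contour data are skipped with a logged warning; a ROI whose
    contour sequence is structurally broken raises :class:`FormatError`.
    """
    ds = pydicom.dcmread(path)
    if getattr(ds, "SOPClassUID", None) != _RTSTRUCT_SOP and ds.Modality != "RTSTRUCT":
        raise FormatError(f"{path}: not an RT-STRUCT file")
    names = {
        int(item.ROINumber): str(item.ROIName)
        for item in getattr(ds, "StructureSetROISequence", [])
    }
    if not names:
        raise FormatError(f"{path}: RT-STRUCT contains no ROIs")
    out: list[RoiContours] = []
    for rc in getattr(ds, "ROIContourSequence", []):
        number = int(rc.ReferencedROINumber)
        name = names.get(number, f"ROI-{number}")
        contour_seq = getattr(rc, "ContourSequence", None)
        if not contour_seq:
            logger.warning("ROI %r has no contour data; skipped", name)
            continue
        slices = []
        for c in contour_seq:
            try:
                data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            except (AttributeError, ValueError) as exc:
                raise FormatError(f"ROI {name!r}: corrupt contour data") from exc
            zs = data[:, 2]
            if not np.allclose(zs, zs[0]):
                raise FormatError(f"ROI {name!r}: contour is not planar in z")
            slices.append((float(zs[0]), data[:, :2]))
        out.append(RoiContours(name=name, slices=slices))
    return out


# ---------------------------------------------------------------------------
# DICOM RT-DOSE
# ---------------------------------------------------------------------------

def write_rtdose(grid: Grid3D, path: str | Path) -> Path:
    """Write a dose grid to DICOM RT-DOSE (32-bit, per-file scaling)."""
    if np.any(grid.values < 0):
        raise ValueError("RT-DOSE requires non-negative dose values")
    path = Path(path)
    nz, ny, nx = grid.shape
    max_dose = float(grid.values.max())
    scaling = max_dose / (2**32 - 1) if max_dose > 0 else 1.0
    stored = np.round(grid.values / scaling).astype(np.uint32)

    ds = _base_dataset(_RTDOSE_SOP, "RTDOSE")
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.ImagePositionPatient = [f"{v:.6f}" for v in grid.origin]
    ds.ImageOrientationPatient = [f"{v:.1f}" for v in _IDENTITY_IOP]
    ds.PixelSpacing = [f"{grid.spacing[1]:.6f}", f"{grid.spacing[0]:.6f}"]  # row, col
    ds.GridFrameOffsetVector = [f"{grid.spacing[2] * k:.6f}" for k in range(nz)]
    ds.FrameIncrementPointer = 0x3004000C  # GridFrameOffsetVector
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = f"{scaling:.9e}"  # <= 16 chars, the DS limit
    ds.PixelData = stored.astype("<u4").tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def read_rtdose(path: str | Path) -> Grid3D:
    """Read an RT-DOSE file into a :class:`Grid3D` of absolute Gy."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "SOPClassUID", None) != _RTDOSE_SOP and ds.Modality != "RTDOSE":
        raise FormatError(f"{path}: not an RT-DOSE file")
    iop = np.asarray(
        getattr(ds, "ImageOrientationPatient", list(_IDENTITY_IOP)), dtype=float
    )
    if not np.allclose(iop, _IDENTITY_IOP):
        raise FormatError("only axis-aligned head-first-supine grids are supported")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if len(offsets) > 1:
        steps = np.diff(offsets)
        if not np.allclose(steps, steps[0], atol=1e-6):
            raise FormatError("non-uniform GridFrameOffsetVector is not supported")
        dz = float(steps[0])
    else:
        dz = 1.0
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    origin = (origin[0], origin[1], origin[2] + float(offsets[0]))
    scaling = float(ds.DoseGridScaling)
    values = ds.pixel_array.astype(float) * scaling
    if values.ndim == 2:
        values = values[None]
    return Grid3D(origin=origin, spacing=(col_sp, row_sp, dz), values=values)


# ---------------------------------------------------------------------------
# Rasterization and resampling
# ---------------------------------------------------------------------------

def _points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd (crossing number) containment test, vectorized over points."""
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    inside = np.zeros(px.shape, dtype=bool)
    for ax, ay, bx, by in zip(x0, y0, x1, y1):
        if ay == by:
            continue  # horizontal edges never cross a horizontal test ray
        crosses = (ay > py) != (by > py)
        x_at = ax + (py - ay) * (bx - ax) / (by - ay)
        inside ^= crosses & (px < x_at)
    return inside


def rasterize(roi: RoiContours, geometry: Grid3D | BinaryMask) -> BinaryMask:
    """Voxelize planar contours onto a grid geometry.

    A voxel is inside iff its center is inside the polygon(s) of the nearest
    contour slice, by the even-odd rule; grid slices with no contour within
    half a slice spacing stay empty.  Multiple polygons on one plane combine
    by exclusive-or (even-odd across polygons), supporting holes.
    """
    xs, ys, zs = geometry.axis_coords()
    dz = geometry.spacing[2]
    voxels = np.zeros((len(zs), len(ys), len(xs)), dtype=bool)
    if not roi.slices:
        logger.warning("ROI %r has no contour slices; empty mask", roi.name)
        return BinaryMask(geometry.origin, geometry.spacing, voxels)

    contour_z = np.array([z for z, _ in roi.slices])
    px, py = np.meshgrid(xs, ys)  # (ny, nx)
    any_hit = False
    for iz, z in enumerate(zs):
        j = int(np.argmin(np.abs(contour_z - z)))
        if abs(contour_z[j] - z) > dz / 2 + 1e-9:
            continue
        plane = np.zeros(px.shape, dtype=bool)
        zc = contour_z[j]
        for z_k, poly in roi.slices:
            if abs(z_k - zc) < 1e-9:
                plane ^= _points_in_polygon(px, py, poly)
        voxels[iz] = plane
        any_hit = any_hit or plane.any()
    if not any_hit:
        logger.warning(
            "ROI %r: no contour slice within half the grid spacing; empty mask",
            roi.name,
        )
    return BinaryMask(geometry.origin, geometry.spacing, voxels)


def resample(src: Grid3D, dst_geometry: Grid3D | BinaryMask) -> Grid3D:
    """Trilinear resample of ``src`` onto another geometry; 0 outside support."""
    if src.same_geometry(dst_geometry):
        return Grid3D(src.origin, src.spacing, src.values.copy())
    sx, sy, sz = src.axis_coords()
    interp = RegularGridInterpolator(
        (sz, sy, sx), src.values, method="linear", bounds_error=False, fill_value=0.0
    )
    dx_, dy_, dz_ = dst_geometry.axis_coords()
    zz, yy, xx = np.meshgrid(dz_, dy_, dx_, indexing="ij")
    pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    values = interp(pts).reshape(zz.shape)
    return Grid3D(
        tuple(dst_geometry.origin), tuple(dst_geometry.spacing), values
    )


# ---------------------------------------------------------------------------
# Internal single-file bundle (arrays + JSON geometry header)
# ---------------------------------------------------------------------------

def save_bundle(path: str | Path, geometry, **arrays: np.ndarray) -> Path:
    """Save arrays with a shared grid geometry to a zip bundle (``.psb``)."""
    path = Path(path)
    header = {
        "origin": list(geometry.origin),
        "spacing": list(geometry.spacing),
        "arrays": {},
    }
    with zipfile.ZipFile(path, "w") as zf:
        for name, arr in arrays.items():
            arr = np.asarray(arr)
            header["arrays"][name] = {"dtype": str(arr.dtype), "shape": list(arr.shape)}
            zf.writestr(name + ".bin", np.ascontiguousarray(arr).tobytes())
        zf.writestr("geometry.json", json.dumps(header))
    return path


def load_bundle(path: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    """Load a bundle; returns (geometry header dict, name -> array)."""
    arrays: dict[str, np.ndarray] = {}
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("geometry.json"))
        for name, info in header["arrays"].items():
            raw = zf.read(name + ".bin")
            arrays[name] = np.frombuffer(raw, dtype=info["dtype"]).reshape(
                info["shape"]
            )
    return header, arrays
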