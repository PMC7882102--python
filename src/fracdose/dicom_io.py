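"""DICOM readers: CT series, RTDOSE and RTSTRUCT onto the package grid model.

Only axis-aligned (identity image-orientation) axial volumes are supported;
arrays are reordered to the package convention of index axes ``[x, y, z]``.
Writing DICOM is out of scope — exports use the portable container.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
from skimage.draw import polygon as _polygon

from .errors import FormatError, ParameterError
from .grids import DoseGrid, ImageVolume, StructureMask

_AXIAL_IOP = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])


def _check_axial(ds) -> None:
    iop = np.asarray(getattr(ds, "ImageOrientationPatient", _AXIAL_IOP), dtype=float)
    if not np.allclose(iop, _AXIAL_IOP, atol=1e-4):
        raise FormatError("only axis-aligned axial volumes are supported")


def read_ct_series(directory) -> ImageVolume:
    """Load a directory of single-slice CT files into one HU volume.

    Slices are sorted by z position; slice spacing must be uniform.  Rescale
    slope/intercept are applied so voxels are Hounsfield units.
    """
    paths = sorted(Path(directory).glob("*.dcm")) or sorted(Path(directory).iterdir())
    datasets = []
    for p in paths:
        if not p.is_file():
            continue
        ds = pydicom.dcmread(str(p))
        if getattr(ds, "Modality", "CT") not in ("CT", "OT"):
            continue
        datasets.append(ds)
    if not datasets:
        raise FormatError(f"no CT slices found in {directory}")
    datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    _check_axial(datasets[0])
    zs = np.array([float(d.ImagePositionPatient[2]) for d in datasets])
    dz = np.diff(zs)
    if len(dz) and not np.allclose(dz, dz[0], atol=1e-3):
        raise FormatError("non-uniform CT slice spacing")
    row_sp, col_sp = (float(v) for v in datasets[0].PixelSpacing)  # (y, x)
    slice_thickness = float(dz[0]) if len(dz) else float(
        getattr(datasets[0], "SliceThickness", 1.0)
    )
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    vol_zyx = np.stack(slices, axis=0)  # (z, y, x)
    voxels = np.ascontiguousarray(vol_zyx.transpose(2, 1, 0))  # (x, y, z)
    ipp = np.asarray(datasets[0].ImagePositionPatient, dtype=float)
    return ImageVolume(
        voxels,
        spacing=np.array([col_sp, row_sp, slice_thickness]),
        origin=ipp,
    )


def read_rtdose(path) -> DoseGrid:
    """Load a DICOM RTDOSE grid (Gy)."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise FormatError(f"{path} is not an RTDOSE file")
    _check_axial(ds)
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    dose_zyx = ds.pixel_array.astype(float) * scaling
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if len(dz) and not np.allclose(dz, dz[0], atol=1e-3):
        raise FormatError("non-uniform RTDOSE frame offsets")
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    ipp = np.asarray(ds.ImagePositionPatient, dtype=float)
    dose = np.ascontiguousarray(dose_zyx.transpose(2, 1, 0))
    return DoseGrid(
        dose,
        spacing=np.array([col_sp, row_sp, float(dz[0]) if len(dz) else 1.0]),
        origin=ipp + np.array([0.0, 0.0, float(offsets[0])]),
    )


def read_rtstruct(path, grid, roi_names=None) -> dict[str, StructureMask]:
    """Rasterize RTSTRUCT contours onto ``grid`` (an ImageVolume or DoseGrid).

    Each contour polygon is filled on the nearest z slice.  Returns a dict of
    masks keyed by ROI name; restrict with ``roi_names``.
    """
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTSTRUCT":
        raise FormatError(f"{path} is not an RTSTRUCT file")
    names = {}
    for roi in ds.StructureSetROISequence:
        names[int(roi.ROINumber)] = str(roi.ROIName)
    shape = grid.shape
    spacing, origin = grid.spacing, grid.origin
    out: dict[str, StructureMask] = {}
    for contour_set in getattr(ds, "ROIContourSequence", []):
        number = int(contour_set.ReferencedROINumber)
        name = names.get(number, f"roi_{number}")
        if roi_names is not None and name not in roi_names:
            continue
        mask = np.zeros(shape, dtype=bool)
        for contour in getattr(contour_set, "ContourSequence", []):
            data = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            if data.shape[0] < 3:
                raise ParameterError(f"ROI {name!r}: contour with < 3 points")
            iz = int(round((data[0, 2] - origin[2]) / spacing[2]))
            if not 0 <= iz < shape[2]:
                continue
            ix = (data[:, 0] - origin[0]) / spacing[0]
            iy = (data[:, 1] - origin[1]) / spacing[1]
            rr, cc = _polygon(iy, ix, shape=(shape[1], shape[0]))
            mask[cc, rr, iz] = True
        out[name] = StructureMask(name, mask, np.asarray(spacing, float).copy(),
                                  np.asarray(origin, float).copy())
    if not out:
        raise FormatError(f"{path}: no matching ROIs found")
    return out
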