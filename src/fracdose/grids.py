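"""Voxel-grid data model and shared geometry operations.

All volumes are axis-aligned, indexed ``[ix, iy, iz]`` so that array axes
coincide with the patient coordinate axes (x, y, z).  The physical position of
a voxel center is ``origin + index * spacing`` (0-based indices, millimetres).
Rigid transforms act on physical coordinates; resampling interpolates
trilinearly for continuous quantities (dose, HU) and nearest-neighbour for
masks.

Conventions fixed here and relied on everywhere else:

* out-of-grid dose reads return 0 Gy (dose supports are interior),
* out-of-grid HU reads return -1000 (air),
* the out-of-field-of-view sentinel HU is -3024, a common scanner convention
  distinguishable from valid air,
* rotations are applied about the fixed axes in x -> y -> z order
  (pitch, roll, yaw) around a stated center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import CalibrationError, ConfigurationError, FormatError, ParameterError

#: Sentinel HU marking voxels outside a limited (CBCT) field of view.
OUT_OF_FOV_HU = -3024.0

#: HU returned for reads outside an image grid.
AIR_HU = -1000.0


def _as_vec3(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ParameterError(f"{name} must have 3 components, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name} must be finite, got {arr}")
    return arr


@dataclass
class ImageVolume:
    """HU image on a regular grid; planning CT or daily CBCT.

    ``fov_radius_mm`` is set for CBCT volumes with a limited cylindrical field
    of view (axis along z through the grid center); voxels outside it carry
    :data:`OUT_OF_FOV_HU`.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    fov_radius_mm: float | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ParameterError("voxels must be a 3D array")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise ParameterError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ParameterError("voxels must be finite")
        if self.fov_radius_mm is not None and self.fov_radius_mm <= 0:
            raise ParameterError("fov_radius_mm must be positive when set")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def grid_center(self) -> np.ndarray:
        """Physical position of the grid center (mm)."""
        return self.origin + (np.array(self.shape) - 1) / 2.0 * self.spacing

    def fov_mask(self) -> np.ndarray:
        """Boolean mask of voxels inside the cylindrical FOV (all True if unlimited)."""
        if self.fov_radius_mm is None:
            return np.ones(self.shape, dtype=bool)
        cx, cy, _ = self.grid_center()
        x = self.origin[0] + np.arange(self.shape[0]) * self.spacing[0]
        y = self.origin[1] + np.arange(self.shape[1]) * self.spacing[1]
        r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
        return np.broadcast_to((r2 <= self.fov_radius_mm**2)[:, :, None], self.shape).copy()


@dataclass
class DoseGrid:
    """Absorbed dose in Gy on its own grid, tagged with a coordinate frame."""

    dose: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    frame_id: str = "planning"

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 3:
            raise ParameterError("dose must be a 3D array")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise ParameterError("spacing must be strictly positive")
        if not np.all(np.isfinite(self.dose)):
            raise ParameterError("dose must be finite")
        if np.any(self.dose < 0):
            raise ParameterError("dose must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dose.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self, **changes) -> "DoseGrid":
        out = replace(self, **changes)
        if "dose" not in changes:
            out.dose = self.dose.copy()
        return out


@dataclass
class StructureMask:
    """Boolean occupancy of one ROI on a named grid."""

    name: str
    mask: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ParameterError("mask must be a 3D array")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise ParameterError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def volume_mm3(self) -> float:
        return self.voxel_count() * float(np.prod(self.spacing))


def same_grid(a, b, atol: float = 1e-6) -> bool:
    """True if two grid objects share shape, spacing and origin."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform:
    """Six-degree-of-freedom rigid transform: the residual setup-error model.

    ``t`` is a translation in mm, ``r_deg`` rotation angles in degrees about
    the fixed x, y, z axes (applied in that order) around ``center`` (mm),
    typically the plan isocenter.  Forward action on a point ``p``:
    ``R @ (p - center) + center + t``.
    """

    t: np.ndarray = field(default_factory=lambda: np.zeros(3))
    r_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.t = _as_vec3(self.t, "t")
        self.r_deg = _as_vec3(self.r_deg, "r_deg")
        self.center = _as_vec3(self.center, "center")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def is_identity(self) -> bool:
        return bool(np.all(self.t == 0) and np.all(self.r_deg == 0))

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix, x -> y -> z order about fixed axes."""
        rx, ry, rz = np.deg2rad(self.r_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Forward-transform an (N, 3) or (3,) array of physical points (mm)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = (self.matrix() @ (p - self.center).T).T + self.center + self.t
        return out.reshape(np.shape(points))

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = (self.matrix().T @ (p - self.center - self.t).T).T + self.center
        return out.reshape(np.shape(points))

    def inverse(self) -> "RigidTransform":
        """Exact inverse as a new transform (rotation transposed, matching center).

        The inverse is returned in matrix form via a small wrapper because the
        Euler angles of the inverse are not simply negated; callers needing
        only point mapping should prefer :meth:`apply_inverse`.
        """
        R = self.matrix().T
        # recover x->y->z Euler angles of R
        ry = np.arcsin(-R[2, 0])
        if abs(np.cos(ry)) > 1e-12:
            rx = np.arctan2(R[2, 1], R[2, 2])
            rz = np.arctan2(R[1, 0], R[0, 0])
        else:  # gimbal lock, irrelevant for small angles but handled
            rx = np.arctan2(-R[1, 2], R[1, 1])
            rz = 0.0
        t_inv = -(R @ self.t)
        return RigidTransform(t=t_inv, r_deg=np.rad2deg([rx, ry, rz]), center=self.center)

    def to_dict(self) -> dict:
        return {
            "translation_mm": self.t.tolist(),
            "rotation_deg": self.r_deg.tolist(),
            "center_mm": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(t=d["translation_mm"], r_deg=d["rotation_deg"], center=d["center_mm"])


def save_transform(path, transform: RigidTransform) -> None:
    with open(path, "w") as fh:
        json.dump(transform.to_dict(), fh, indent=1)


def load_transform(path) -> RigidTransform:
    with open(path) as fh:
        return RigidTransform.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# HU-to-density calibration
# ---------------------------------------------------------------------------


@dataclass
class HUDensityCurve:
    """Piecewise-linear HU -> relative electron density calibration.

    Evaluation clamps beyond the end points.  One curve per modality (planning
    CT and CBCT are calibrated separately).
    """

    hu: np.ndarray
    density: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=float).reshape(-1)
        self.density = np.asarray(self.density, dtype=float).reshape(-1)
        if self.hu.size < 2:
            raise CalibrationError("HU curve needs at least 2 control points")
        if self.hu.size != self.density.size:
            raise CalibrationError("HU and density lists must have equal length")
        if np.any(np.diff(self.hu) <= 0):
            raise CalibrationError("HU control points must be strictly increasing")
        if np.any(self.density < 0) or np.any(np.diff(self.density) < 0):
            raise CalibrationError("densities must be non-negative and non-decreasing")

    @classmethod
    def from_points(cls, points, label: str = "") -> "HUDensityCurve":
        pts = np.asarray(points, dtype=float)
        return cls(hu=pts[:, 0], density=pts[:, 1], label=label)

    def __call__(self, hu) -> np.ndarray:
        return np.interp(hu, self.hu, self.density)

    def shifted(self, hu_offset: float, label: str = "") -> "HUDensityCurve":
        """Same densities at HU control points offset by ``hu_offset``.

        Used to calibrate a modality whose HU scale is shifted relative to the
        planning CT (the usual CBCT situation).  A zero offset returns an
        identical curve.
        """
        if hu_offset == 0:
            return HUDensityCurve(self.hu.copy(), self.density.copy(), label or self.label)
        return HUDensityCurve(self.hu + hu_offset, self.density.copy(), label or self.label)


#: Generic water-equivalent calibration used as the planning-CT default.
DEFAULT_HU_CURVE = HUDensityCurve(
    hu=np.array([-1000.0, -200.0, 0.0, 200.0, 1000.0, 3000.0]),
    density=np.array([0.0, 0.80, 1.00, 1.10, 1.52, 2.50]),
    label="planning_ct",
)


def apply_hu_curve(vol: ImageVolume, curve: HUDensityCurve) -> np.ndarray:
    """Map an HU volume voxelwise to relative electron density.

    Out-of-FOV sentinel voxels are left unset (NaN) so a downstream stitching
    step can fill them; stitched volumes contain no sentinels and produce a
    fully finite density volume.
    """
    density = np.asarray(curve(vol.voxels), dtype=float)
    marker = vol.voxels <= OUT_OF_FOV_HU
    if np.any(marker):
        density = density.copy()
        density[marker] = np.nan
    return density


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def _resample_array(
    values: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray,
    transform: RigidTransform,
    cval: float,
    order: int = 1,
) -> np.ndarray:
    """Pull-back resample: output(o) = values at T^-1(x_o), same grid.

    Implemented as a single affine map in index space so scipy's spline
    filter-free linear path does the interpolation.
    """
    if transform.is_identity():
        return values.copy()
    R = transform.matrix()
    S = np.asarray(spacing, dtype=float)
    A = (R.T / S[:, None]) * S[None, :]  # diag(1/S) @ R.T @ diag(S)
    shift = R.T @ (origin - transform.t - transform.center) + transform.center - origin
    b = shift / S
    return ndimage.affine_transform(
        values, A, offset=b, order=order, mode="constant", cval=cval, prefilter=False
    )


def resample_dose(dose: DoseGrid, transform: RigidTransform) -> DoseGrid:
    """Rigidly move a dose cloud and resample it back onto its own grid.

    Each output voxel takes the trilinear interpolation of the input dose at
    the inverse-transformed voxel-center position; positions falling outside
    the grid read 0 Gy.  The identity transform returns a bit-identical copy.
    """
    if not (np.all(np.isfinite(transform.t)) and np.all(np.isfinite(transform.r_deg))):
        raise ParameterError("transform parameters must be finite")
    if dose.dose.size == 0:
        raise ParameterError("dose grid is empty")
    out = _resample_array(dose.dose, dose.spacing, dose.origin, transform, cval=0.0)
    # trilinear interpolation of non-negative data is non-negative up to rounding
    np.clip(out, 0.0, None, out=out)
    return DoseGrid(out, dose.spacing.copy(), dose.origin.copy(), dose.frame_id)


def resample_mask(mask: StructureMask, transform: RigidTransform) -> StructureMask:
    """Nearest-neighbour rigid resampling of a structure mask."""
    if transform.is_identity():
        return StructureMask(mask.name, mask.mask.copy(), mask.spacing.copy(), mask.origin.copy())
    out = _resample_array(
        mask.mask.astype(np.float32), mask.spacing, mask.origin, transform, cval=0.0, order=0
    )
    return StructureMask(mask.name, out > 0.5, mask.spacing.copy(), mask.origin.copy())


def stitch_limited_fov(
    cbct: ImageVolume, planning: ImageVolume, registration: RigidTransform
) -> ImageVolume:
    """Complete a limited-FOV CBCT with planning-CT HU outside the FOV cylinder.

    ``registration`` is the online couch-match transform mapping the planning
    frame into the fraction frame; outside the FOV the planning CT is read
    through its inverse.  The result carries no out-of-FOV sentinels.
    """
    if cbct.fov_radius_mm is None:
        raise ConfigurationError("cbct volume has no fov_radius_mm set")
    if not same_grid(cbct, planning):
        raise FrameError("cbct and planning volumes must share a grid")
    inside = cbct.fov_mask()
    filled = _resample_array(
        planning.voxels, planning.spacing, planning.origin, registration, cval=AIR_HU
    )
    out = np.where(inside, cbct.voxels, filled)
    # any sentinel leaking through inside the FOV would poison density mapping
    out[out <= OUT_OF_FOV_HU] = AIR_HU
    return ImageVolume(out, cbct.spacing.copy(), cbct.origin.copy(), fov_radius_mm=None)


def expand_body_region(body: StructureMask, margin_mm: float) -> StructureMask:
    """Isotropic morphological expansion of the body outline by ``margin_mm``.

    Uses a Euclidean distance transform threshold, so the expansion is
    spherical in physical space regardless of anisotropic spacing; the result
    always contains the input and is clipped at the grid bounds.
    """
    if margin_mm < 0:
        raise ParameterError("margin_mm must be non-negative")
    if margin_mm == 0 or not body.mask.any():
        return StructureMask(body.name, body.mask.copy(), body.spacing.copy(), body.origin.copy())
    dist = ndimage.distance_transform_edt(~body.mask, sampling=body.spacing)
    return StructureMask(
        body.name, dist <= margin_mm, body.spacing.copy(), body.origin.copy()
    )


# ---------------------------------------------------------------------------
# Portable single-file container
# ---------------------------------------------------------------------------

_MAGIC = "fracdose-grid 1"


def _header(kind: str, arr: np.ndarray, spacing, origin, **extra) -> bytes:
    meta = {
        "format": _MAGIC,
        "kind": kind,
        "shape": list(arr.shape),
        "dtype": arr.dtype.str,  # includes byte order
        "spacing_mm": list(np.asarray(spacing, dtype=float)),
        "origin_mm": list(np.asarray(origin, dtype=float)),
    }
    meta.update(extra)
    return (json.dumps(meta) + "\n").encode("utf-8")


def save_grid(path, obj) -> None:
    """Write an ImageVolume / DoseGrid / StructureMask to the portable container.

    The container is a JSON metadata line followed by the raw little-endian
    array bytes (C order); round trips are bit exact.  Masks are stored as
    8-bit {0, 1}.
    """
    if isinstance(obj, ImageVolume):
        arr = np.ascontiguousarray(obj.voxels, dtype="<f8")
        head = _header("image", arr, obj.spacing, obj.origin, fov_radius_mm=obj.fov_radius_mm)
    elif isinstance(obj, DoseGrid):
        arr = np.ascontiguousarray(obj.dose, dtype="<f8")
        head = _header("dose", arr, obj.spacing, obj.origin, frame_id=obj.frame_id)
    elif isinstance(obj, StructureMask):
        arr = np.ascontiguousarray(obj.mask.astype(np.uint8))
        head = _header("mask", arr, obj.spacing, obj.origin, name=obj.name)
    else:
        raise ParameterError(f"cannot serialize object of type {type(obj).__name__}")
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(arr.tobytes(order="C"))


def load_grid(path):
    """Read back a portable container written by :func:`save_grid`."""
    with open(path, "rb") as fh:
        head = fh.readline()
        try:
            meta = json.loads(head.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise FormatError(f"{path}: not a fracdose grid container") from exc
        if meta.get("format") != _MAGIC:
            raise FormatError(f"{path}: unsupported container format {meta.get('format')!r}")
        shape = tuple(meta["shape"])
        dtype = np.dtype(meta["dtype"])
        raw = fh.read(int(np.prod(shape)) * dtype.itemsize)
    arr = np.frombuffer(raw, dtype=dtype).reshape(shape).copy()
    kind = meta["kind"]
    if kind == "image":
        return ImageVolume(arr, meta["spacing_mm"], meta["origin_mm"], meta.get("fov_radius_mm"))
    if kind == "dose":
        return DoseGrid(arr, meta["spacing_mm"], meta["origin_mm"], meta.get("frame_id", "planning"))
    if kind == "mask":
        return StructureMask(meta.get("name", "roi"), arr > 0, meta["spacing_mm"], meta["origin_mm"])
    raise FormatError(f"{path}: unknown container kind {kind!r}")
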