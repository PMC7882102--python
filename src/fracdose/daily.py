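"""Daily (CBCT-based) dose estimation, comparison and accumulation.

The commercial dose engines used clinically for CBCT-based delivered-dose
reconstruction are full superposition/convolution algorithms.  This module
instead declares a *primary-fluence path-length perturbation model*: per
beam, the delivered dose at a voxel is the planned dose scaled by
``exp(-mu_eff * (depth_daily - depth_plan))`` where the depths are
radiological (density-weighted) path lengths from the beam source to the
voxel and ``mu_eff`` is an effective linear attenuation coefficient per unit
relative-electron-density path.  The default ``mu_eff = 0.0035 / mm``
(~3.5 %/cm) matches the depth-dose falloff of a 10-MV photon beam in water
beyond the build-up region.  Identical daily and planning anatomy reproduces
the planned dose exactly; the model captures the mechanism-level effects of
weight change (extra upstream tissue attenuates) and gas pockets (missing
tissue boosts) without claiming engine equivalence.

Beam geometry is coplanar: gantry angle 0 places the source anteriorly at
``iso + SAD * (sin g, cos g, 0)`` and the beam travels in the axial plane.
For whole-volume depth maps the rays of a beam are treated as parallel to its
central axis (< 2 % divergence error for a 1000-mm SAD over a pelvic
volume); :func:`radiological_depth` provides the exact divergent-ray line
integral for point queries and validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .dvh import DVHMetrics, dvh_metrics, relative_difference
from .errors import (
    DegenerateROIError,
    EmptyCourseError,
    FrameError,
    GeometryError,
    InsufficientDataError,
    ParameterError,
)
from .grids import (
    DoseGrid,
    ImageVolume,
    RigidTransform,
    StructureMask,
    _resample_array,
    resample_dose,
    same_grid,
)

logger = logging.getLogger("fracdose.daily")


@dataclass
class BeamModel:
    """Coplanar beam arrangement plus the attenuation parameter of the dose model."""

    gantry_angles_deg: np.ndarray
    weights: np.ndarray
    mu_eff: float = 0.0035  # 1/mm of unit-density path; ~3.5%/cm for 10 MV in water
    sad_mm: float = 1000.0

    def __post_init__(self):
        self.gantry_angles_deg = np.asarray(self.gantry_angles_deg, dtype=float).reshape(-1)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if self.gantry_angles_deg.size != self.weights.size:
            raise ParameterError("one weight per beam required")
        if np.any(self.weights <= 0):
            raise ParameterError("beam weights must be positive")
        if self.mu_eff <= 0:
            raise ParameterError("mu_eff must be positive")
        if self.sad_mm <= 0:
            raise ParameterError("sad_mm must be positive")

    @classmethod
    def equispaced(cls, n_beams: int = 7, start_deg: float = 0.0, **kwargs) -> "BeamModel":
        """Equispaced coplanar beams with equal weights (7 or 9 typical)."""
        angles = start_deg + np.arange(n_beams) * 360.0 / n_beams
        return cls(gantry_angles_deg=angles, weights=np.full(n_beams, 1.0 / n_beams), **kwargs)

    def direction(self, i: int) -> np.ndarray:
        """Unit propagation direction of beam ``i`` (source toward isocenter)."""
        g = np.deg2rad(self.gantry_angles_deg[i])
        return -np.array([np.sin(g), np.cos(g), 0.0])

    def source_position(self, i: int, isocenter) -> np.ndarray:
        g = np.deg2rad(self.gantry_angles_deg[i])
        return np.asarray(isocenter, dtype=float) + self.sad_mm * np.array(
            [np.sin(g), np.cos(g), 0.0]
        )


@dataclass
class FractionRecord:
    """One treatment fraction: imaging, registration and estimated delivered dose."""

    fraction_index: int
    cbct: ImageVolume | None = None
    registration: RigidTransform = field(default_factory=RigidTransform.identity)
    delivered_dose: DoseGrid | None = None
    excluded: bool = False
    reason: str = ""


@dataclass
class DeformationField:
    """Per-voxel displacement (mm) mapping planning-frame positions to fraction frame.

    Consumed only — deformable registration itself is outside this package.
    """

    displacement: np.ndarray  # (nx, ny, nz, 3) mm
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
            raise ParameterError("displacement must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacement)):
            raise ParameterError("displacement vectors must be finite")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]


# ---------------------------------------------------------------------------
# Radiological depth
# ---------------------------------------------------------------------------


def radiological_depth(
    density: np.ndarray,
    spacing,
    origin,
    source,
    point,
    step_mm: float | None = None,
) -> float:
    """Equivalent path length (mm of unit-density material) from source to point.

    Uniform-step midpoint ray marching of the trilinearly interpolated density
    along the source -> point segment; the step defaults to half the minimum
    spacing, making the integral exact for piecewise-constant densities up to
    step resolution.  Density outside the grid reads 0 (air).
    """
    density = np.asarray(density, dtype=float)
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    origin = np.asarray(origin, dtype=float).reshape(3)
    if not np.all(np.isfinite(density)) or np.any(density < 0):
        raise ParameterError("density must be finite and non-negative")
    source = np.asarray(source, dtype=float).reshape(3)
    point = np.asarray(point, dtype=float).reshape(3)
    hull_lo = origin
    hull_hi = origin + (np.array(density.shape) - 1) * spacing
    if np.all(source >= hull_lo) and np.all(source <= hull_hi):
        raise GeometryError("beam source lies inside the density volume")
    if step_mm is None:
        step_mm = float(spacing.min()) / 2.0
    if step_mm <= 0:
        raise ParameterError("step_mm must be positive")
    seg = point - source
    length = float(np.linalg.norm(seg))
    if length == 0:
        return 0.0
    # clip the segment to the interpolation hull: outside it density is 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (hull_lo - source) / seg
        t_hi = (hull_hi - source) / seg
    t_min = np.where(np.isnan(t_lo), -np.inf, np.minimum(t_lo, t_hi))
    t_max = np.where(np.isnan(t_hi), np.inf, np.maximum(t_lo, t_hi))
    t0 = max(float(np.max(t_min)), 0.0)
    t1 = min(float(np.min(t_max)), 1.0)
    if t1 <= t0:
        return 0.0
    seg_len = (t1 - t0) * length
    n = max(int(np.ceil(seg_len / step_mm)), 1)
    ts = t0 + (np.arange(n) + 0.5) * (t1 - t0) / n
    pts = source[None, :] + ts[:, None] * seg[None, :]
    idx = (pts - origin) / spacing
    samples = ndimage.map_coordinates(
        density, idx.T, order=1, mode="constant", cval=0.0, prefilter=False
    )
    return float(samples.sum() * seg_len / n)


def _rotate_about_z(values: np.ndarray, spacing, origin, angle_deg: float, center) -> np.ndarray:
    """Resample ``values`` so the world is rotated by ``angle_deg`` about z around center."""
    tr = RigidTransform(r_deg=np.array([0.0, 0.0, angle_deg]), center=center)
    return _resample_array(values, np.asarray(spacing, float), np.asarray(origin, float), tr, cval=0.0)


def beam_depth_map(
    density: np.ndarray, spacing, origin, gantry_deg: float, isocenter
) -> np.ndarray:
    """Radiological depth of every voxel for one beam, parallel-ray geometry.

    The density is resampled into the beam frame (rays anti-parallel to +y),
    depths accumulate by a midpoint cumulative sum along the ray axis, and the
    depth map is resampled back onto the original grid.
    """
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    rho = _rotate_about_z(density, spacing, origin, gantry_deg, isocenter)
    # entry side is +y (source side); midpoint rule within each voxel
    csum = np.cumsum(rho[:, ::-1, :], axis=1)[:, ::-1, :]
    depth_rot = (csum - 0.5 * rho) * spacing[1]
    return _rotate_about_z(depth_rot, spacing, origin, -gantry_deg, isocenter)


# ---------------------------------------------------------------------------
# Fraction dose estimation and comparison
# ---------------------------------------------------------------------------


def fraction_dose_estimate(
    planned: DoseGrid,
    planning_density: np.ndarray,
    daily_density: np.ndarray,
    beams: BeamModel,
    isocenter,
    region: StructureMask | None = None,
) -> DoseGrid:
    """Estimate the dose delivered on the daily anatomy from the planned dose.

    Per voxel v: ``delivered(v) = planned(v) * sum_b w_b exp(-mu_eff *
    (depth_daily_b(v) - depth_plan_b(v))) / sum_b w_b``.  Voxels outside the
    calculation ``region`` (body outline + margin) copy the planned dose.
    Identical anatomies return the planned dose bit-for-bit.
    """
    planning_density = np.asarray(planning_density, dtype=float)
    daily_density = np.asarray(daily_density, dtype=float)
    if planning_density.shape != planned.shape or daily_density.shape != planned.shape:
        raise FrameError("density volumes must be on the planning dose grid")
    if not (np.all(np.isfinite(planning_density)) and np.all(np.isfinite(daily_density))):
        raise ParameterError("density volumes must be finite (stitch limited-FOV inputs first)")
    if np.array_equal(daily_density, planning_density):
        return planned.copy(frame_id=planned.frame_id)
    w = beams.weights
    factor = np.zeros(planned.shape)
    for i in range(w.size):
        d_plan = beam_depth_map(
            planning_density, planned.spacing, planned.origin, beams.gantry_angles_deg[i], isocenter
        )
        d_daily = beam_depth_map(
            daily_density, planned.spacing, planned.origin, beams.gantry_angles_deg[i], isocenter
        )
        factor += w[i] * np.exp(-beams.mu_eff * (d_daily - d_plan))
    factor /= w.sum()
    delivered = planned.dose * factor
    if region is not None:
        if not same_grid(planned, region):
            raise FrameError("calculation region must be on the planning grid")
        delivered = np.where(region.mask, delivered, planned.dose)
    return DoseGrid(delivered, planned.spacing.copy(), planned.origin.copy(), planned.frame_id)


def delivered_in_planning_frame(record: FractionRecord, planned: DoseGrid) -> DoseGrid:
    """Map a fraction's delivered dose into the planning frame.

    If the delivered dose is already tagged with the planning frame it is
    returned as-is; otherwise it is resampled through the inverse of the
    online registration (planning -> fraction), i.e. the planning-frame value
    at x reads the fraction-frame dose at registration(x).
    """
    dose = record.delivered_dose
    if dose is None:
        raise ParameterError(f"fraction {record.fraction_index} has no delivered dose")
    if dose.frame_id == planned.frame_id:
        return dose
    out = resample_dose(dose, record.registration.inverse())
    return DoseGrid(out.dose, out.spacing, out.origin, planned.frame_id)


def compare_fraction(
    planned: DoseGrid,
    record: FractionRecord,
    rois: dict[str, StructureMask],
    prescription: float = 0.0,
) -> list[dict] | None:
    """Per-ROI relative DVH-metric differences of one fraction vs its planned dose.

    Returns one row per ROI, or None for an excluded fraction (logged, not an
    error).  Sign convention: positive = delivered lower than planned.
    """
    if record.excluded:
        logger.info(
            "fraction %d excluded from comparison: %s", record.fraction_index, record.reason
        )
        return None
    delivered = delivered_in_planning_frame(record, planned)
    rows = []
    for name, roi in rois.items():
        pm = dvh_metrics(planned, roi, prescription)
        dm = dvh_metrics(delivered, roi, prescription)
        diff = relative_difference(pm, dm)
        rows.append(
            {
                "fraction": record.fraction_index,
                "roi": name,
                "dd98_pct": diff["d98"],
                "dd2_pct": diff["d2"],
                "ddmean_pct": diff["dmean"],
            }
        )
    return rows


def accumulate_rigid(
    records: list[FractionRecord],
    planned_total: DoseGrid,
    rois: dict[str, StructureMask] | None = None,
    n_planned: int | None = None,
    prescription: float = 0.0,
):
    """Accumulate per-fraction delivered doses in the planning frame.

    Excluded fractions are omitted and the sum is rescaled by
    ``n_planned / n_included`` so the accumulated dose stays comparable to
    the planned course total.  The planned reference total is reconstituted
    by summing the per-fraction planned dose with the same accumulation
    arithmetic, so that identical delivered fractions reproduce zero
    difference exactly.

    Returns ``(accumulated DoseGrid, per-ROI difference DataFrame, info)``.
    """
    if n_planned is None:
        n_planned = len(records)
    included = [r for r in records if not r.excluded]
    if not included:
        raise EmptyCourseError("all fractions are excluded")
    excluded = [(r.fraction_index, r.reason) for r in records if r.excluded]
    included = sorted(included, key=lambda r: r.fraction_index)

    acc = np.zeros(planned_total.shape)
    for rec in included:
        acc = acc + delivered_in_planning_frame(rec, planned_total).dose
    scale = n_planned / len(included)
    if scale != 1.0:
        acc = acc * scale
        logger.info(
            "accumulation: %d of %d fractions included; scaling by %d/%d",
            len(included), n_planned, n_planned, len(included),
        )
    accumulated = DoseGrid(
        acc, planned_total.spacing.copy(), planned_total.origin.copy(), planned_total.frame_id
    )

    planned_fraction = planned_total.dose * (1.0 / n_planned)
    ref = np.zeros(planned_total.shape)
    for _ in range(n_planned):
        ref = ref + planned_fraction
    reference = DoseGrid(
        ref, planned_total.spacing.copy(), planned_total.origin.copy(), planned_total.frame_id
    )

    rows = []
    if rois:
        for name, roi in rois.items():
            pm = dvh_metrics(reference, roi, prescription)
            am = dvh_metrics(accumulated, roi, prescription)
            diff = relative_difference(pm, am)
            rows.append(
                {
                    "roi": name,
                    "dd98_pct": diff["d98"],
                    "dd2_pct": diff["d2"],
                    "ddmean_pct": diff["dmean"],
                }
            )
    info = {
        "n_planned": n_planned,
        "n_included": len(included),
        "scale": scale,
        "excluded": excluded,
    }
    return accumulated, pd.DataFrame(rows), info


# ---------------------------------------------------------------------------
# Registration QA and deformation
# ---------------------------------------------------------------------------


def dice_coefficient(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|) of two masks."""
    if not same_grid(a, b):
        raise FrameError("masks must share a grid")
    na, nb = a.voxel_count(), b.voxel_count()
    if na == 0 and nb == 0:
        raise DegenerateROIError("both masks are empty; DSC undefined")
    inter = int(np.count_nonzero(a.mask & b.mask))
    return 2.0 * inter / (na + nb)


def apply_deformation(dose: DoseGrid, dvf: DeformationField) -> DoseGrid:
    """Pull a fraction-frame dose back onto the planning grid through a DVF.

    ``output(v) = dose(x_v + displacement(v))`` with trilinear interpolation;
    no Jacobian (energy/mass) weighting is applied.  Displacements mapping
    outside the fraction grid read 0 Gy; the affected voxel count is logged.
    """
    if dvf.shape != dose.shape or not (
        np.allclose(dvf.spacing, dose.spacing) and np.allclose(dvf.origin, dose.origin)
    ):
        raise FrameError("deformation field must live on the dose grid")
    shape = dose.shape
    ax = [dose.origin[k] + np.arange(shape[k]) * dose.spacing[k] for k in range(3)]
    xs, ys, zs = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([xs, ys, zs], axis=-1) + dvf.displacement
    idx = (pts - dose.origin) / dose.spacing
    out_of_grid = np.any((idx < 0) | (idx > np.array(shape) - 1), axis=-1)
    n_out = int(out_of_grid.sum())
    if n_out:
        logger.info("deformation maps %d voxels outside the fraction grid (zero-filled)", n_out)
    warped = ndimage.map_coordinates(
        dose.dose,
        idx.reshape(-1, 3).T,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    ).reshape(shape)
    np.clip(warped, 0.0, None, out=warped)
    return DoseGrid(warped, dose.spacing.copy(), dose.origin.copy(), "planning")


# ---------------------------------------------------------------------------
# Paired comparison test
# ---------------------------------------------------------------------------


@dataclass
class PairedTestResult:
    """Classical paired t test with explicit handling of the zero-variance case."""

    n: int
    mean_diff: float
    sd_diff: float
    t_statistic: float
    p_value: float
    degenerate: bool
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < self.alpha


def paired_comparison_test(a, b, alpha: float = 0.05) -> PairedTestResult:
    """Student's paired t test between two matched samples.

    When every pairwise difference is identical the t statistic is undefined
    (zero variance); the result is flagged degenerate instead of raising.
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.size != b.size:
        raise ParameterError("paired samples must have equal length")
    if a.size < 2:
        raise InsufficientDataError("paired t test needs at least 2 observations")
    diffs = a - b
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        return PairedTestResult(
            n=a.size, mean_diff=float(diffs.mean()), sd_diff=0.0,
            t_statistic=np.nan, p_value=np.nan, degenerate=True, alpha=alpha,
        )
    t_stat, p = stats.ttest_rel(a, b)
    return PairedTestResult(
        n=a.size, mean_diff=float(diffs.mean()), sd_diff=sd,
        t_statistic=float(t_stat), p_value=float(p), degenerate=False, alpha=alpha,
    )
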