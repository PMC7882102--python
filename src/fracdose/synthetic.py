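"""Synthetic pelvic phantom, plan, daily-anatomy and trajectory-log generators.

Everything the pipeline consumes can be generated here, seeded and
deterministic: a pelvic CT phantom built from ellipsoids and tubes (body,
CTV, 7-mm PTV margin, bladder, rectum, femoral heads, bone), a prescription
dose with a plateau covering the PTV and a sigmoid penumbra, daily anatomies
with body-contour (weight) change, organ-filling variation and rectal gas
pockets imaged as limited-FOV CBCT with HU offset and noise, analytic
(invertible) radial deformation fields, and trajectory logs with injected
MLC/MU error laws.

Phantom realism is deliberately minimal: the analysis surface of this
package is mechanism-level (how anatomy changes move dose metrics), not
anatomical fidelity.  Zero-magnitude variation configs reproduce the
planning anatomy exactly, voxel for voxel, so null pipelines report exactly
zero differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import FeasibilityError, GeometryError, ParameterError
from .grids import (
    AIR_HU,
    OUT_OF_FOV_HU,
    DoseGrid,
    ImageVolume,
    RigidTransform,
    StructureMask,
    _resample_array,
)
from .daily import DeformationField
from .trajectory import (
    MAX_LEAF_SPEED_MM_S,
    MILLENNIUM_120_WIDTHS,
    ControlPointSequence,
    TrajectoryLog,
)

# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


@dataclass
class PhantomConfig:
    """Geometry and tissue parameters of the pelvic phantom.

    Default grid: 144 x 144 x 96 voxels at 2 mm (the dose-calculation
    resolution), centered on the isocenter.  The body is an elliptic cylinder
    cross-section (axial semi-axes ``body_semiaxes`` mm) clipped by the grid
    in z, wider than the 26-cm CBCT field of view so limited-FOV stitching is
    exercised.
    """

    shape: tuple = (144, 144, 96)
    spacing: tuple = (2.0, 2.0, 2.0)
    body_semiaxes: tuple = (140.0, 100.0, 120.0)
    ctv_radius_mm: float = 30.0
    ptv_margin_mm: float = 7.0
    bladder_radius_mm: float = 20.0
    bladder_center: tuple = (0.0, 55.0, 0.0)
    rectum_radius_mm: float = 15.0
    rectum_center_y: float = -50.0
    rectum_half_length_mm: float = 60.0
    femoral_head_radius_mm: float = 22.0
    femoral_head_centers: tuple = ((90.0, -10.0, 0.0), (-90.0, -10.0, 0.0))
    spine_radius_mm: float = 14.0
    spine_center_y: float = -85.0
    spine_half_length_mm: float = 50.0
    soft_tissue_hu: float = 40.0
    bone_hu: float = 700.0
    bladder_hu: float = 0.0
    rectum_hu: float = 20.0
    gas_hu: float = -1000.0
    seed: int = 0

    @property
    def origin(self) -> np.ndarray:
        shp = np.array(self.shape, dtype=float)
        sp = np.array(self.spacing, dtype=float)
        return -(shp - 1) / 2.0 * sp


@dataclass
class Phantom:
    """Planning CT, structure set and isocenter of one synthetic case."""

    ct: ImageVolume
    structures: dict
    isocenter: np.ndarray
    config: PhantomConfig


def _axes(shape, spacing, origin):
    return [origin[k] + np.arange(shape[k]) * spacing[k] for k in range(3)]


def _ellipsoid(axes, center, semiaxes) -> np.ndarray:
    x, y, z = axes
    sa = np.asarray(semiaxes, dtype=float)
    q = (
        ((x - center[0]) / sa[0])[:, None, None] ** 2
        + ((y - center[1]) / sa[1])[None, :, None] ** 2
        + ((z - center[2]) / sa[2])[None, None, :] ** 2
    )
    return q <= 1.0


def _sphere(axes, center, radius) -> np.ndarray:
    return _ellipsoid(axes, center, (radius, radius, radius))


def _z_cylinder(axes, center_xy, radius, z_lo, z_hi) -> np.ndarray:
    x, y, z = axes
    disk = ((x - center_xy[0])[:, None] ** 2 + (y - center_xy[1])[None, :] ** 2) <= radius**2
    zsel = (z >= z_lo) & (z <= z_hi)
    return disk[:, :, None] & zsel[None, None, :]


def _body_mask(axes, semiaxes) -> np.ndarray:
    """Elliptic cross-section tapered in z like a truncated ellipsoid."""
    x, y, z = axes
    sa = np.asarray(semiaxes, dtype=float)
    taper2 = np.clip(1.0 - (z / sa[2]) ** 2, 0.0, None)
    q = (x / sa[0])[:, None, None] ** 2 + (y / sa[1])[None, :, None] ** 2
    return q <= taper2[None, None, :]


def _check_inside_grid(mask: np.ndarray, name: str) -> None:
    if not mask.any():
        raise GeometryError(f"structure {name!r} is empty (zero size or outside grid)")
    if (
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    ):
        raise GeometryError(f"structure {name!r} touches the grid boundary")


def _paint_anatomy(config: PhantomConfig, body_semiaxes, organ_scales=None, gas_spheres=()):
    """HU volume + organ masks for one anatomy instance (planning or daily)."""
    shape = tuple(config.shape)
    spacing = np.array(config.spacing, dtype=float)
    origin = config.origin
    axes = _axes(shape, spacing, origin)
    scales = {"bladder": 1.0, "rectum": 1.0}
    if organ_scales:
        scales.update(organ_scales)

    if min(
        config.ctv_radius_mm, config.bladder_radius_mm,
        config.rectum_radius_mm, config.femoral_head_radius_mm,
    ) <= 0:
        raise GeometryError("all organ radii must be positive")

    body = _body_mask(axes, body_semiaxes)
    ctv = _sphere(axes, (0.0, 0.0, 0.0), config.ctv_radius_mm)
    # organ filling modeled as a volume scale factor -> cube-root radius scale
    bl_r = config.bladder_radius_mm * scales["bladder"] ** (1.0 / 3.0)
    bladder = _sphere(axes, config.bladder_center, bl_r)
    re_r = config.rectum_radius_mm * scales["rectum"] ** (1.0 / 3.0)
    rectum = _z_cylinder(
        axes, (0.0, config.rectum_center_y), re_r,
        -config.rectum_half_length_mm, config.rectum_half_length_mm,
    )
    fh_r = _sphere(axes, config.femoral_head_centers[0], config.femoral_head_radius_mm)
    fh_l = _sphere(axes, config.femoral_head_centers[1], config.femoral_head_radius_mm)
    spine = _z_cylinder(
        axes, (0.0, config.spine_center_y), config.spine_radius_mm,
        -config.spine_half_length_mm, config.spine_half_length_mm,
    )
    bone = fh_r | fh_l | spine

    hu = np.full(shape, AIR_HU)
    hu[body] = config.soft_tissue_hu
    hu[bone & body] = config.bone_hu
    hu[bladder & body] = config.bladder_hu
    hu[rectum & body] = config.rectum_hu
    gas_mask = np.zeros(shape, dtype=bool)
    for center, radius in gas_spheres:
        gas_mask |= _sphere(axes, center, radius)
    gas_mask &= body
    hu[gas_mask] = config.gas_hu

    masks = {
        "body": body, "ctv": ctv, "bladder": bladder, "rectum": rectum,
        "femoral_head_r": fh_r, "femoral_head_l": fh_l, "bone": bone,
    }
    if gas_mask.any():
        masks["gas"] = gas_mask
    return hu, masks


def make_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Build the planning CT and structure set; deterministic given the config."""
    config = config or PhantomConfig()
    spacing = np.array(config.spacing, dtype=float)
    origin = config.origin
    hu, raw = _paint_anatomy(config, config.body_semiaxes)

    for name in ("ctv", "bladder", "rectum", "femoral_head_r", "femoral_head_l"):
        _check_inside_grid(raw[name], name)
    for name in ("bladder", "rectum", "femoral_head_r", "femoral_head_l"):
        if (raw[name] & raw["ctv"]).any():
            raise GeometryError(f"organ {name!r} overlaps the CTV")

    # PTV: isotropic expansion of the CTV by the planning margin
    dist = ndimage.distance_transform_edt(~raw["ctv"], sampling=spacing)
    ptv = dist <= config.ptv_margin_mm
    _check_inside_grid(ptv, "ptv")

    structures = {
        name: StructureMask(name, mask, spacing.copy(), origin.copy())
        for name, mask in {**raw, "ptv": ptv}.items()
    }
    ct = ImageVolume(hu, spacing, origin)
    return Phantom(ct=ct, structures=structures, isocenter=np.zeros(3), config=config)


# ---------------------------------------------------------------------------
# Plan dose
# ---------------------------------------------------------------------------


def make_plan_dose(
    phantom: Phantom,
    prescription: float = 50.4,
    falloff_mm: float = 5.0,
    plateau_scale: float = 1.02,
) -> DoseGrid:
    """Prescription-level plateau over the PTV with a sigmoid penumbra.

    The dose is ``plateau_scale * Rx / (1 + exp((s - falloff)/ (falloff/4)))``
    where ``s`` is the signed distance to the PTV surface (negative inside),
    putting the 50% level ~``falloff_mm`` outside the PTV.  With the default
    2% plateau overshoot the plan satisfies all three PTV coverage goals and
    the CTV sits on a uniform plateau extending the full PTV margin beyond
    it.
    """
    if falloff_mm <= 0:
        raise ParameterError("falloff_mm must be positive")
    if prescription < 0:
        raise ParameterError("prescription must be non-negative")
    ptv = phantom.structures["ptv"]
    if prescription == 0:
        warnings.warn("zero prescription: returning an all-zero dose (degenerate plan)")
        return DoseGrid(
            np.zeros(ptv.shape), ptv.spacing.copy(), ptv.origin.copy(), "planning"
        )
    outside = ndimage.distance_transform_edt(~ptv.mask, sampling=ptv.spacing)
    inside = ndimage.distance_transform_edt(ptv.mask, sampling=ptv.spacing)
    sdist = outside - inside
    dose = plateau_scale * prescription / (1.0 + np.exp((sdist - falloff_mm) / (falloff_mm / 4.0)))
    return DoseGrid(dose, ptv.spacing.copy(), ptv.origin.copy(), "planning")


# ---------------------------------------------------------------------------
# Daily anatomies
# ---------------------------------------------------------------------------


@dataclass
class DailyVariationConfig:
    """Interfractional variation model for the daily CBCT series.

    Weight change is a radial (axial) body-contour change in mm with a
    systematic per-fraction drift plus a zero-mean random component; the
    default drift reaches ~14 mm over 28 fractions, emulating a pronounced
    belly-size change.  Gas pockets appear in the rectum with a per-fraction
    probability.  CBCT degradation is a constant HU offset plus Gaussian
    noise inside a 26-cm-diameter field of view.  All-zero magnitudes
    reproduce the planning anatomy exactly.
    """

    weight_drift_mm_per_fraction: float = 0.5
    weight_sd_mm: float = 1.0
    gas_probability: float = 0.15
    gas_radius_range_mm: tuple = (8.0, 15.0)
    bladder_filling_sd: float = 0.10
    rectum_filling_sd: float = 0.10
    cbct_hu_offset: float = 15.0
    cbct_noise_sd_hu: float = 20.0
    fov_diameter_mm: float = 260.0
    setup_error_mm: float = 0.0
    setup_error_deg: float = 0.0
    seed: int = 0

    def is_null(self) -> bool:
        return (
            self.weight_drift_mm_per_fraction == 0 and self.weight_sd_mm == 0
            and self.gas_probability == 0 and self.bladder_filling_sd == 0
            and self.rectum_filling_sd == 0 and self.cbct_hu_offset == 0
            and self.cbct_noise_sd_hu == 0 and self.setup_error_mm == 0
            and self.setup_error_deg == 0
        )


@dataclass
class DailyFraction:
    """Generated inputs of one fraction plus its ground-truth parameters."""

    fraction_index: int
    cbct: ImageVolume
    registration: RigidTransform
    structures: dict
    params: dict


def make_daily_series(
    phantom: Phantom,
    n_fractions: int = 28,
    variation: DailyVariationConfig | None = None,
) -> list[DailyFraction]:
    """Generate the per-fraction CBCT series with seeded daily variation.

    Per fraction the body semi-axes change by ``drift * k + N(0, sd)`` mm
    (axially), organ filling scales are drawn, gas pockets appear with the
    configured probability, a residual setup-error transform is drawn (the
    anatomy is imaged in the displaced fraction frame), and the image is
    cropped to the FOV cylinder with HU offset and noise applied inside.
    """
    variation = variation or DailyVariationConfig()
    config = phantom.config
    rng = np.random.default_rng(variation.seed)
    base = np.array(config.body_semiaxes, dtype=float)
    fractions = []
    for k in range(1, n_fractions + 1):
        delta = variation.weight_drift_mm_per_fraction * k + rng.normal(
            0.0, variation.weight_sd_mm
        )
        semiaxes = base + np.array([delta, delta, 0.0])
        scales = {
            "bladder": float(
                np.clip(1.0 + rng.normal(0.0, variation.bladder_filling_sd), 0.7, 1.3)
            ),
            "rectum": float(
                np.clip(1.0 + rng.normal(0.0, variation.rectum_filling_sd), 0.7, 1.3)
            ),
        }
        gas_spheres = []
        if rng.uniform() < variation.gas_probability:
            radius = rng.uniform(*variation.gas_radius_range_mm)
            z = rng.uniform(
                -config.rectum_half_length_mm / 2.0, config.rectum_half_length_mm / 2.0
            )
            gas_spheres.append(((0.0, config.rectum_center_y, float(z)), float(radius)))

        hu, masks = _paint_anatomy(config, semiaxes, scales, gas_spheres)

        # residual setup error: the anatomy is imaged in the fraction frame
        t_mag = rng.uniform(0.0, variation.setup_error_mm, 3) * rng.choice([-1.0, 1.0], 3)
        r_mag = rng.uniform(0.0, variation.setup_error_deg, 3) * rng.choice([-1.0, 1.0], 3)
        registration = RigidTransform(t=t_mag, r_deg=r_mag, center=phantom.isocenter)
        spacing = np.array(config.spacing, dtype=float)
        origin = config.origin
        if not registration.is_identity():
            hu = _resample_array(hu, spacing, origin, registration, cval=AIR_HU)
            masks = {
                name: _resample_array(m.astype(np.float32), spacing, origin, registration,
                                      cval=0.0, order=0) > 0.5
                for name, m in masks.items()
            }

        noise = rng.normal(0.0, variation.cbct_noise_sd_hu, hu.shape)
        cbct_hu = hu + variation.cbct_hu_offset + noise
        fov_radius = variation.fov_diameter_mm / 2.0
        probe = ImageVolume(cbct_hu, spacing, origin, fov_radius_mm=fov_radius)
        out = ~probe.fov_mask()
        cbct_hu[out] = OUT_OF_FOV_HU
        cbct = ImageVolume(cbct_hu, spacing, origin.copy(), fov_radius_mm=fov_radius)

        structures = {
            name: StructureMask(name, m, spacing.copy(), origin.copy())
            for name, m in masks.items()
        }
        fractions.append(
            DailyFraction(
                fraction_index=k,
                cbct=cbct,
                registration=registration,
                structures=structures,
                params={
                    "body_delta_mm": float(delta),
                    "organ_scales": scales,
                    "gas_spheres": gas_spheres,
                },
            )
        )
    return fractions


# ---------------------------------------------------------------------------
# Analytic deformation fields
# ---------------------------------------------------------------------------


@dataclass
class RadialWarp:
    """Invertible radial Gaussian-bump warp with closed-form forward mapping.

    Forward: ``y = x + a * exp(-r^2 / (2 sigma^2)) * r_hat`` about ``center``
    (an organ-filling-style local expansion).  The radial map
    ``g(r) = r + a exp(-r^2/2sigma^2)`` is strictly increasing when
    ``a < sigma * e^{1/2} / 1`` scaled by the max-slope bound; the inverse is
    evaluated by Newton iteration on g, giving a machine-precision oracle.
    """

    center: np.ndarray
    amplitude_mm: float
    sigma_mm: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.sigma_mm <= 0:
            raise ParameterError("sigma_mm must be positive")
        # max |du/dr| = a/sigma * exp(-1/2); require headroom for invertibility
        if abs(self.amplitude_mm) / self.sigma_mm * np.exp(-0.5) >= 0.95:
            raise ParameterError("warp magnitude too large to be invertible")

    def _u(self, r: np.ndarray) -> np.ndarray:
        return self.amplitude_mm * np.exp(-(r**2) / (2.0 * self.sigma_mm**2))

    def displacement(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points) - self.center
        r = np.linalg.norm(p, axis=-1, keepdims=True)
        rhat = np.divide(p, r, out=np.zeros_like(p), where=r > 0)
        return (self._u(r) * rhat).reshape(np.shape(points))

    def forward(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + self.displacement(points)

    def inverse(self, points: np.ndarray, tol: float = 1e-10, max_iter: int = 50) -> np.ndarray:
        """Newton inversion of the scalar radial map, vectorized over points."""
        q = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        R = np.linalg.norm(q, axis=-1)
        r = R.copy()
        for _ in range(max_iter):
            g = r + self._u(r) - R
            dg = 1.0 - r / self.sigma_mm**2 * self._u(r)
            step = g / dg
            r = r - step
            if np.all(np.abs(step) < tol):
                break
        scale = np.divide(r, R, out=np.ones_like(R), where=R > 0)
        out = self.center + q * scale[..., None]
        return out.reshape(np.shape(points))

    def as_deformation_field(self, shape, spacing, origin) -> DeformationField:
        axes = _axes(tuple(shape), np.asarray(spacing, float), np.asarray(origin, float))
        xs, ys, zs = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([xs, ys, zs], axis=-1)
        disp = self.displacement(pts.reshape(-1, 3)).reshape(pts.shape)
        return DeformationField(disp, spacing, origin)


def make_analytic_dvf(
    phantom: Phantom, center=None, amplitude_mm: float = 5.0, sigma_mm: float = 30.0
) -> tuple[DeformationField, RadialWarp]:
    """Closed-form radial DVF on the phantom grid, with its warp object for oracles."""
    if center is None:
        center = phantom.isocenter
    warp = RadialWarp(center=center, amplitude_mm=amplitude_mm, sigma_mm=sigma_mm)
    ct = phantom.ct
    return warp.as_deformation_field(ct.shape, ct.spacing, ct.origin), warp


# ---------------------------------------------------------------------------
# Trajectory logs
# ---------------------------------------------------------------------------


@dataclass
class LogErrorModel:
    """Injected machine-control error laws for synthetic trajectory logs.

    MLC: per-leaf per-sample Gaussian, ``bias + N(0, sd)`` mm (one shared
    draw per sample if ``per_leaf_correlated``).  MU: a positive delivery lag
    subtracted from the expected cumulative MU, drawn from an exponential law
    of the given mean and held constant over blocks of samples (a servo-drift
    timescale), which keeps the actual MU stream monotone at realistic dose
    rates.  A zero-parameter model yields actual == expected exactly.
    """

    mlc_bias_mm: float = 0.0
    mlc_sd_mm: float = 0.0
    mu_lag_mean_mu: float = 0.0
    mu_lag_block_samples: int = 50
    per_leaf_correlated: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.mlc_sd_mm < 0 or self.mu_lag_mean_mu < 0:
            raise ParameterError("error magnitudes must be non-negative")
        if self.mu_lag_block_samples < 1:
            raise ParameterError("mu_lag_block_samples must be >= 1")


def make_control_points(
    n_control_points: int = 50,
    field_width_mm: float = 100.0,
    field_height_mm: float = 100.0,
    window_mm: float = 20.0,
    total_mu: float = 218.0,
    leaf_widths: np.ndarray | None = None,
) -> ControlPointSequence:
    """Sliding-window DMLC beam: an open window sweeping across the field.

    Leaf pairs overlapping the jaw y-window carry a ``window_mm``-wide gap
    whose position advances linearly with MU fraction; the remaining pairs
    are parked closed at the field edge.
    """
    if leaf_widths is None:
        leaf_widths = MILLENNIUM_120_WIDTHS.copy()
    leaf_widths = np.asarray(leaf_widths, dtype=float)
    n_pairs = leaf_widths.size
    edges = np.concatenate([[0.0], np.cumsum(leaf_widths)]) - leaf_widths.sum() / 2.0
    active = (edges[1:] > -field_height_mm / 2.0) & (edges[:-1] < field_height_mm / 2.0)

    mu_fraction = np.linspace(0.0, 1.0, n_control_points)
    start = -field_width_mm / 2.0
    travel = field_width_mm - window_mm
    lead = start + mu_fraction * travel
    bank_a = np.full((n_control_points, n_pairs), start)
    bank_b = np.full((n_control_points, n_pairs), start)  # parked closed
    bank_a[:, active] = lead[:, None]
    bank_b[:, active] = lead[:, None] + window_mm
    jaw = np.array(
        [start - 5.0, field_width_mm / 2.0 + 5.0, -field_height_mm / 2.0, field_height_mm / 2.0]
    )
    return ControlPointSequence(
        bank_a=bank_a, bank_b=bank_b, mu_fraction=mu_fraction,
        leaf_widths=leaf_widths, jaw=jaw, total_mu=total_mu,
    )


def make_trajectory_log(
    cps: ControlPointSequence,
    model: LogErrorModel | None = None,
    duration_s: float = 20.0,
    sampling_ms: float = 20.0,
    beam_id: str = "beam",
    gantry_deg: float = 0.0,
) -> TrajectoryLog:
    """Sample a DMLC delivery of ``cps`` at the log time resolution.

    The expected stream interpolates control points at a constant dose rate;
    a control-point segment demanding more than the 2.5 cm/s leaf-speed limit
    is rejected as infeasible.  The actual stream adds the injected error
    laws of ``model``.
    """
    model = model or LogErrorModel()
    if duration_s <= 0 or sampling_ms <= 0:
        raise ParameterError("duration and sampling interval must be positive")
    # feasibility: leaf speed within each control-point segment
    d_mu = np.diff(cps.mu_fraction)
    for bank in (cps.bank_a, cps.bank_b):
        d_pos = np.abs(np.diff(bank, axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            speed = d_pos / (d_mu[:, None] * duration_s)
        still = d_mu[:, None] == 0
        if np.any(d_pos[np.broadcast_to(still, d_pos.shape)] > 0):
            raise FeasibilityError("leaf motion requested at zero MU advance")
        if np.nanmax(np.where(still, 0.0, speed), initial=0.0) > MAX_LEAF_SPEED_MM_S:
            raise FeasibilityError(
                f"plan requires leaf speed above {MAX_LEAF_SPEED_MM_S / 10.0:.1f} cm/s"
            )

    n = int(round(duration_s * 1000.0 / sampling_ms)) + 1
    frac = np.linspace(0.0, 1.0, n)
    mu_expected = frac * cps.total_mu
    p = cps.n_pairs
    bank_a_exp = np.empty((n, p))
    bank_b_exp = np.empty((n, p))
    for j in range(p):
        bank_a_exp[:, j] = np.interp(frac, cps.mu_fraction, cps.bank_a[:, j])
        bank_b_exp[:, j] = np.interp(frac, cps.mu_fraction, cps.bank_b[:, j])

    rng = np.random.default_rng(model.seed)
    if model.mlc_bias_mm == 0 and model.mlc_sd_mm == 0:
        bank_a_act = bank_a_exp.copy()
        bank_b_act = bank_b_exp.copy()
    else:
        def draw(shape):
            if model.per_leaf_correlated:
                return np.broadcast_to(
                    rng.normal(model.mlc_bias_mm, model.mlc_sd_mm, (shape[0], 1)), shape
                ).copy()
            return rng.normal(model.mlc_bias_mm, model.mlc_sd_mm, shape)

        bank_a_act = bank_a_exp + draw((n, p))
        bank_b_act = bank_b_exp + draw((n, p))

    if model.mu_lag_mean_mu == 0:
        mu_actual = mu_expected.copy()
    else:
        n_blocks = int(np.ceil(n / model.mu_lag_block_samples))
        lags = rng.exponential(model.mu_lag_mean_mu, n_blocks)
        lag_per_sample = np.repeat(lags, model.mu_lag_block_samples)[:n]
        mu_actual = np.clip(mu_expected - lag_per_sample, 0.0, None)
        mu_actual = np.maximum.accumulate(mu_actual)

    jaw = np.broadcast_to(cps.jaw, (n, 4)).copy()
    gantry = np.full(n, gantry_deg)
    return TrajectoryLog(
        sampling_interval_ms=sampling_ms,
        beam_id=beam_id,
        mu_expected=mu_expected, mu_actual=mu_actual,
        gantry_expected=gantry, gantry_actual=gantry.copy(),
        jaw_expected=jaw, jaw_actual=jaw.copy(),
        bank_a_expected=bank_a_exp, bank_a_actual=bank_a_act,
        bank_b_expected=bank_b_exp, bank_b_actual=bank_b_act,
    )


def small_phantom_config(**overrides) -> PhantomConfig:
    """A scaled-down phantom (64^3 at 3 mm) for fast multi-course studies.

    Geometry is shrunk proportionally so all structures keep their anatomical
    relations; intended for statistical properties that need many courses.
    """
    cfg = PhantomConfig(
        shape=(64, 64, 48),
        spacing=(3.0, 3.0, 3.0),
        body_semiaxes=(88.0, 64.0, 80.0),
        ctv_radius_mm=20.0,
        ptv_margin_mm=7.0,
        bladder_radius_mm=13.0,
        bladder_center=(0.0, 36.0, 0.0),
        rectum_radius_mm=9.0,
        rectum_center_y=-33.0,
        rectum_half_length_mm=40.0,
        femoral_head_radius_mm=13.0,
        femoral_head_centers=((56.0, -8.0, 0.0), (-56.0, -8.0, 0.0)),
        spine_radius_mm=9.0,
        spine_center_y=-52.0,
        spine_half_length_mm=30.0,
    )
    return replace(cfg, **overrides)
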