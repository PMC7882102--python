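"""Grid model, rigid resampling, HU calibration, FOV stitching, container I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracdose import (
    AIR_HU,
    OUT_OF_FOV_HU,
    CalibrationError,
    ConfigurationError,
    DoseGrid,
    HUDensityCurve,
    ImageVolume,
    ParameterError,
    RigidTransform,
    StructureMask,
    apply_hu_curve,
    expand_body_region,
    load_grid,
    load_transform,
    resample_dose,
    save_grid,
    save_transform,
    stitch_limited_fov,
)


class TestRigidTransform:
    def test_identity_leaves_points_unchanged(self, rng):
        pts = rng.uniform(-100, 100, (20, 3))
        assert np.array_equal(RigidTransform.identity().apply(pts), pts)

    def test_inverse_composition_is_identity(self, rng):
        tr = RigidTransform(t=(1.5, -0.7, 0.3), r_deg=(1.0, -2.0, 0.5), center=(10, -5, 3))
        pts = rng.uniform(-100, 100, (50, 3))
        assert np.abs(tr.apply_inverse(tr.apply(pts)) - pts).max() < 1e-9
        assert np.abs(tr.inverse().apply(tr.apply(pts)) - pts).max() < 1e-9

    def test_rotation_is_about_center(self):
        tr = RigidTransform(r_deg=(0, 0, 90), center=(5, 5, 0))
        assert np.allclose(tr.apply(np.array([5.0, 5.0, 0.0])), [5, 5, 0])
        assert np.allclose(tr.apply(np.array([6.0, 5.0, 0.0])), [5, 6, 0])

    def test_json_round_trip(self, tmp_path):
        tr = RigidTransform(t=(1, 2, 3), r_deg=(0.5, -0.25, 1), center=(0, 0, 10))
        save_transform(tmp_path / "t.json", tr)
        back = load_transform(tmp_path / "t.json")
        assert np.array_equal(back.t, tr.t)
        assert np.array_equal(back.r_deg, tr.r_deg)
        assert np.array_equal(back.center, tr.center)


class TestResampleDose:
    def test_identity_is_bit_identical(self, random_dose):
        out = resample_dose(random_dose, RigidTransform.identity())
        assert np.array_equal(out.dose, random_dose.dose)

    def test_one_voxel_translation_equals_index_shift(self, random_dose):
        # dose is zero at the boundary, so rolling is the exact oracle
        tr = RigidTransform(t=(random_dose.spacing[0], 0, 0))
        out = resample_dose(random_dose, tr)
        assert np.allclose(out.dose, np.roll(random_dose.dose, 1, axis=0), atol=1e-12)

    def test_uniform_field_interior_invariant_under_small_shift(self):
        dose = DoseGrid(np.full((30, 30, 30), 50.4), (2, 2, 2), (0, 0, 0))
        out = resample_dose(dose, RigidTransform(t=(2.0, 0.0, 0.0)))
        assert np.allclose(out.dose[4:-4, 4:-4, 4:-4], 50.4)

    def test_nonfinite_transform_rejected(self, random_dose):
        with pytest.raises(ParameterError):
            resample_dose(random_dose, RigidTransform(t=(np.nan, 0, 0)))

    def test_output_bounded_by_input(self, random_dose, rng):
        tr = RigidTransform(t=rng.uniform(-3, 3, 3), r_deg=rng.uniform(-2, 2, 3),
                            center=(24, 24, 24))
        out = resample_dose(random_dose, tr)
        assert out.dose.min() >= 0.0
        assert out.dose.max() <= random_dose.dose.max() + 1e-12

    def test_energy_bound_and_conservation(self, band_limited_dose, rng):
        """Integral dose never grows; it is conserved for interior supports."""
        vin = band_limited_dose.dose.sum()
        center = (np.array(band_limited_dose.shape) - 1) / 2.0 * band_limited_dose.spacing
        for _ in range(5):
            tr = RigidTransform(t=rng.uniform(-2, 2, 3), r_deg=rng.uniform(-2, 2, 3),
                                center=center)
            vout = resample_dose(band_limited_dose, tr).dose.sum()
            assert vout <= vin * (1 + 1e-6)  # no growth beyond interpolation noise
            # support lies well inside the grid; 2 mm / 2 deg cannot reach the edge
            assert vout == pytest.approx(vin, rel=1e-6)

    def test_round_trip_within_interpolation_tolerance(self, band_limited_dose):
        center = (np.array(band_limited_dose.shape) - 1) / 2.0 * band_limited_dose.spacing
        tr = RigidTransform(t=(1.5, -1.0, 0.8), r_deg=(1.2, -0.8, 1.5), center=center)
        there = resample_dose(band_limited_dose, tr)
        back = resample_dose(there, tr.inverse())
        err = np.abs(back.dose - band_limited_dose.dose).max()
        assert err < 0.01 * band_limited_dose.dose.max()


class TestHUCurve:
    CURVE = HUDensityCurve.from_points([(-1000, 0.0), (0, 1.0), (1000, 1.5)])

    @pytest.mark.parametrize(
        "hu,expected",
        [(0.0, 1.0), (500.0, 1.25), (2000.0, 1.5), (-2000.0, 0.0), (-500.0, 0.5)],
    )
    def test_piecewise_linear_with_clamping(self, hu, expected):
        assert self.CURVE(hu) == pytest.approx(expected)

    def test_too_few_points_rejected(self):
        with pytest.raises(CalibrationError):
            HUDensityCurve(hu=[0.0], density=[1.0])

    def test_non_monotone_hu_rejected(self):
        with pytest.raises(CalibrationError):
            HUDensityCurve(hu=[0.0, -10.0, 100.0], density=[1.0, 1.1, 1.2])

    def test_decreasing_density_rejected(self):
        with pytest.raises(CalibrationError):
            HUDensityCurve(hu=[-100.0, 0.0, 100.0], density=[1.0, 0.5, 1.2])

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-3000, 4000), st.floats(-3000, 4000))
    def test_evaluation_is_monotone(self, a, b):
        lo, hi = min(a, b), max(a, b)
        assert self.CURVE(lo) <= self.CURVE(hi)

    def test_out_of_fov_voxels_left_unset(self):
        vox = np.full((4, 4, 4), 0.0)
        vox[0, 0, 0] = OUT_OF_FOV_HU
        vol = ImageVolume(vox, (1, 1, 1), (0, 0, 0), fov_radius_mm=100)
        density = apply_hu_curve(vol, self.CURVE)
        assert np.isnan(density[0, 0, 0])
        assert np.all(density[1:] == 1.0)


class TestStitchLimitedFov:
    def _planning(self, shape=(40, 40, 10)):
        vox = np.full(shape, AIR_HU)
        vox[5:35, 5:35, :] = 40.0  # body block wider than the FOV
        return ImageVolume(vox, (2, 2, 2), (0, 0, 0))

    def test_identical_inputs_reproduce_planning(self):
        planning = self._planning()
        cbct_vox = planning.voxels.copy()
        probe = ImageVolume(cbct_vox, planning.spacing, planning.origin, fov_radius_mm=20)
        cbct_vox = np.where(probe.fov_mask(), cbct_vox, OUT_OF_FOV_HU)
        cbct = ImageVolume(cbct_vox, planning.spacing, planning.origin, fov_radius_mm=20)
        out = stitch_limited_fov(cbct, planning, RigidTransform.identity())
        assert np.array_equal(out.voxels, planning.voxels)
        assert out.fov_radius_mm is None

    def test_offset_confined_to_fov_cylinder(self):
        planning = self._planning()
        probe = ImageVolume(planning.voxels, planning.spacing, planning.origin, fov_radius_mm=20)
        inside = probe.fov_mask()
        cbct_vox = np.where(inside, planning.voxels + 100.0, OUT_OF_FOV_HU)
        cbct = ImageVolume(cbct_vox, planning.spacing, planning.origin, fov_radius_mm=20)
        out = stitch_limited_fov(cbct, planning, RigidTransform.identity())
        diff = out.voxels - planning.voxels
        assert np.all(diff[inside] == 100.0)
        assert np.all(diff[~inside] == 0.0)

    def test_body_preserved_outside_fov(self):
        """Planning body extending beyond the FOV survives stitching."""
        planning = self._planning()
        probe = ImageVolume(planning.voxels, planning.spacing, planning.origin, fov_radius_mm=20)
        cbct_vox = np.where(probe.fov_mask(), planning.voxels, OUT_OF_FOV_HU)
        cbct = ImageVolume(cbct_vox, planning.spacing, planning.origin, fov_radius_mm=20)
        out = stitch_limited_fov(cbct, planning, RigidTransform.identity())
        body_planning = planning.voxels > -300
        body_stitched = out.voxels > -300
        assert np.array_equal(body_planning, body_stitched)
        assert not np.any(out.voxels <= OUT_OF_FOV_HU)

    def test_missing_fov_radius_rejected(self):
        planning = self._planning()
        cbct = ImageVolume(planning.voxels.copy(), planning.spacing, planning.origin)
        with pytest.raises(ConfigurationError):
            stitch_limited_fov(cbct, planning, RigidTransform.identity())


class TestExpandBodyRegion:
    def test_zero_margin_is_identity(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[3:7, 3:7, 3:7] = True
        body = StructureMask("body", mask, (2, 2, 2), (0, 0, 0))
        out = expand_body_region(body, 0.0)
        assert np.array_equal(out.mask, mask)

    def test_sphere_expansion_matches_analytic_volume(self):
        shape = (80, 80, 80)
        spacing = np.array([2.0, 2.0, 2.0])
        origin = -(np.array(shape) - 1) / 2.0 * spacing
        ax = [origin[k] + np.arange(shape[k]) * spacing[k] for k in range(3)]
        r2 = (
            ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
        )
        body = StructureMask("body", r2 <= 50.0**2, spacing, origin)
        out = expand_body_region(body, 20.0)
        analytic = 4.0 / 3.0 * np.pi * 70.0**3
        assert out.volume_mm3() == pytest.approx(analytic, rel=0.02)
        assert np.all(out.mask[body.mask])

    def test_expansion_clipped_at_grid_edge(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[0:3, 0:3, 0:3] = True
        body = StructureMask("body", mask, (2, 2, 2), (0, 0, 0))
        out = expand_body_region(body, 20.0)  # no error, clipped
        assert out.shape == body.shape
        assert out.voxel_count() > body.voxel_count()

    def test_negative_margin_rejected(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ParameterError):
            expand_body_region(StructureMask("body", mask, (1, 1, 1), (0, 0, 0)), -1.0)


class TestContainer:
    def test_round_trips_are_bit_exact(self, tmp_path, rng):
        vol = ImageVolume(rng.normal(0, 500, (6, 5, 4)), (2, 2, 3), (-5, -4, -3),
                          fov_radius_mm=130.0)
        dose = DoseGrid(rng.uniform(0, 60, (6, 5, 4)), (2, 2, 2), (0, 0, 0), frame_id="fx3")
        mask = StructureMask("ctv", rng.uniform(size=(6, 5, 4)) > 0.5, (2, 2, 2), (1, 2, 3))
        for name, obj in (("v", vol), ("d", dose), ("m", mask)):
            save_grid(tmp_path / f"{name}.fgrid", obj)
            back = load_grid(tmp_path / f"{name}.fgrid")
            assert type(back) is type(obj)
            assert np.array_equal(back.spacing, obj.spacing)
            assert np.array_equal(back.origin, obj.origin)
        back_vol = load_grid(tmp_path / "v.fgrid")
        assert np.array_equal(back_vol.voxels, vol.voxels)
        assert back_vol.fov_radius_mm == vol.fov_radius_mm
        back_dose = load_grid(tmp_path / "d.fgrid")
        assert np.array_equal(back_dose.dose, dose.dose)
        assert back_dose.frame_id == "fx3"
        back_mask = load_grid(tmp_path / "m.fgrid")
        assert np.array_equal(back_mask.mask, mask.mask)
        assert back_mask.name == "ctv"

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "bad.fgrid"
        path.write_bytes(b"not a container\n\x00\x01")
        from fracdose import FormatError

        with pytest.raises(FormatError):
            load_grid(path)


class TestValidation:
    def test_negative_spacing_rejected(self):
        with pytest.raises(ParameterError):
            ImageVolume(np.zeros((2, 2, 2)), (1, -1, 1), (0, 0, 0))

    def test_negative_dose_rejected(self):
        with pytest.raises(ParameterError):
            DoseGrid(np.full((2, 2, 2), -1.0), (1, 1, 1), (0, 0, 0))

    def test_nonfinite_voxels_rejected(self):
        vox = np.zeros((2, 2, 2))
        vox[0, 0, 0] = np.inf
        with pytest.raises(ParameterError):
            ImageVolume(vox, (1, 1, 1), (0, 0, 0))
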