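"""Radiological depth, path-length dose model, accumulation, DSC, deformation."""

import numpy as np
import pytest
from scipy import stats as sps

from fracdose import (
    BeamModel,
    DeformationField,
    DegenerateROIError,
    DoseGrid,
    EmptyCourseError,
    FractionRecord,
    FrameError,
    GeometryError,
    InsufficientDataError,
    RigidTransform,
    StructureMask,
    accumulate_rigid,
    apply_deformation,
    compare_fraction,
    dice_coefficient,
    fraction_dose_estimate,
    mean_dose,
    paired_comparison_test,
    radiological_depth,
)

SP = (1.0, 1.0, 1.0)


def water_block(shape=(40, 120, 20)):
    """Unit-density block filling the whole grid, origin centered in x/z."""
    return np.ones(shape)


class TestRadiologicalDepth:
    def test_uniform_density_straight_path(self):
        dens = water_block()
        origin = (-19.5, -59.5, -9.5)
        # path from outside (+y) down to y = -40: hull entry at y = 59.5
        depth = radiological_depth(dens, SP, origin, (0, 500, 0), (0, -40, 0))
        assert depth == pytest.approx(99.5, rel=0.01)

    def test_air_gap_reduces_depth(self):
        dens = water_block()
        origin = (-19.5, -59.5, -9.5)
        dens[:, 80:100, :] = 0.0  # 20 mm air gap at y in [20.5, 40.5)
        depth = radiological_depth(dens, SP, origin, (0, 500, 0), (0, -40, 0))
        assert depth == pytest.approx(99.5 - 20.0, rel=0.01)

    def test_bone_slab_increases_depth(self):
        dens = water_block()
        origin = (-19.5, -59.5, -9.5)
        dens[:, 80:90, :] = 1.5  # 10 mm bone slab
        depth = radiological_depth(dens, SP, origin, (0, 500, 0), (0, -40, 0))
        assert depth == pytest.approx(99.5 + 5.0, rel=0.01)

    def test_source_inside_volume_rejected(self):
        dens = water_block()
        with pytest.raises(GeometryError):
            radiological_depth(dens, SP, (-19.5, -59.5, -9.5), (0, 0, 0), (0, -40, 0))


def _slab_geometry():
    """Water block with CTV sphere; beam from +y; 1 mm grid."""
    shape = (60, 100, 40)
    origin = (-29.5, -49.5, -19.5)
    x = origin[0] + np.arange(shape[0])
    y = origin[1] + np.arange(shape[1])
    z = origin[2] + np.arange(shape[2])
    body = (
        (np.abs(x)[:, None, None] <= 25)
        & (y[None, :, None] >= -40) & (y[None, :, None] <= 20)
        & (np.abs(z)[None, None, :] <= 15)
    )
    plan_density = np.zeros(shape)
    plan_density[body] = 1.0
    ctv = np.zeros(shape, dtype=bool)
    ctv[(x[:, None, None] ** 2 + (y[None, :, None] + 10) ** 2 + z[None, None, :] ** 2) <= 100] = True
    dose = DoseGrid(np.full(shape, 1.8), SP, origin)
    ctv_mask = StructureMask("ctv", ctv, SP, origin)
    beams = BeamModel(gantry_angles_deg=[0.0], weights=[1.0])
    return shape, origin, x, y, z, plan_density, dose, ctv_mask, beams


class TestFractionDoseEstimate:
    def test_identical_anatomy_is_bit_exact(self):
        *_, plan_density, dose, ctv, beams = _slab_geometry()
        out = fraction_dose_estimate(dose, plan_density, plan_density.copy(), beams, (0, 0, 0))
        assert np.array_equal(out.dose, dose.dose)

    def test_upstream_slab_matches_closed_form(self):
        shape, origin, x, y, z, plan_density, dose, ctv, beams = _slab_geometry()
        daily = plan_density.copy()
        slab = (
            (np.abs(x)[:, None, None] <= 25)
            & (y[None, :, None] > 20) & (y[None, :, None] <= 35)
            & (np.abs(z)[None, None, :] <= 15)
        )
        daily[slab] = 1.0  # 15 mm extra tissue upstream
        out = fraction_dose_estimate(dose, plan_density, daily, beams, (0, 0, 0))
        ratio = mean_dose(out, ctv) / mean_dose(dose, ctv)
        assert ratio == pytest.approx(np.exp(-beams.mu_eff * 15.0), rel=0.005)

    def test_gas_pocket_matches_closed_form(self):
        shape, origin, x, y, z, plan_density, dose, _, beams = _slab_geometry()
        daily = plan_density.copy()
        pocket = (
            (np.abs(x)[:, None, None] <= 25)
            & (y[None, :, None] > -5) & (y[None, :, None] <= 15)
            & (np.abs(z)[None, None, :] <= 15)
        )
        daily[pocket] = 0.0  # 20 mm gas upstream of the target region
        target = np.zeros(shape, dtype=bool)
        target[(x[:, None, None] ** 2 + (y[None, :, None] + 25) ** 2
                + z[None, None, :] ** 2) <= 64] = True
        roi = StructureMask("t", target, SP, origin)
        out = fraction_dose_estimate(dose, plan_density, daily, beams, (0, 0, 0))
        ratio = mean_dose(out, roi) / mean_dose(dose, roi)
        assert ratio == pytest.approx(np.exp(beams.mu_eff * 20.0), rel=0.005)

    def test_direction_law_monotone_in_thickness(self):
        """More upstream tissue -> strictly lower CTV mean dose, and vice versa."""
        shape, origin, x, y, z, plan_density, dose, ctv, beams = _slab_geometry()
        means = []
        for thickness in (0, 4, 8, 12, 16):
            daily = plan_density.copy()
            slab = (
                (np.abs(x)[:, None, None] <= 25)
                & (y[None, :, None] > 20) & (y[None, :, None] <= 20 + thickness)
                & (np.abs(z)[None, None, :] <= 15)
            )
            daily[slab] = 1.0
            out = fraction_dose_estimate(dose, plan_density, daily, beams, (0, 0, 0))
            means.append(mean_dose(out, ctv))
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_mismatched_grids_rejected(self):
        *_, plan_density, dose, ctv, beams = _slab_geometry()
        with pytest.raises(FrameError):
            fraction_dose_estimate(dose, plan_density, plan_density[:-1], beams, (0, 0, 0))

    def test_region_mask_limits_recomputation(self):
        shape, origin, x, y, z, plan_density, dose, ctv, beams = _slab_geometry()
        daily = plan_density * 0.5  # global density change
        nothing = StructureMask("region", np.zeros(shape, dtype=bool), SP, origin)
        out = fraction_dose_estimate(dose, plan_density, daily, beams, (0, 0, 0), region=nothing)
        assert np.array_equal(out.dose, dose.dose)  # everything outside region copies planned


class TestCompareAndAccumulate:
    def _planned(self):
        dose = np.zeros((16, 16, 16))
        dose[4:12, 4:12, 4:12] = 50.4
        planned = DoseGrid(dose, (2, 2, 2), (0, 0, 0))
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[6:10, 6:10, 6:10] = True
        return planned, {"ctv": StructureMask("ctv", mask, (2, 2, 2), (0, 0, 0))}

    def test_identical_delivery_zero_differences(self):
        planned, rois = self._planned()
        rec = FractionRecord(1, delivered_dose=planned.copy())
        rows = compare_fraction(planned, rec, rois)
        assert rows[0]["dd98_pct"] == 0.0 and rows[0]["ddmean_pct"] == 0.0

    def test_scaled_delivery_gives_two_percent(self):
        planned, rois = self._planned()
        rec = FractionRecord(1, delivered_dose=planned.copy(dose=planned.dose * 0.98))
        rows = compare_fraction(planned, rec, rois)
        assert rows[0]["dd98_pct"] == pytest.approx(2.0)
        assert rows[0]["dd2_pct"] == pytest.approx(2.0)

    def test_excluded_fraction_skipped(self):
        planned, rois = self._planned()
        rec = FractionRecord(1, excluded=True, reason="corrupt")
        assert compare_fraction(planned, rec, rois) is None

    def test_perfect_course_accumulates_exactly(self):
        planned, rois = self._planned()
        pf = planned.dose * (1.0 / 28)
        records = [
            FractionRecord(k, delivered_dose=DoseGrid(pf, planned.spacing, planned.origin))
            for k in range(1, 29)
        ]
        acc, table, info = accumulate_rigid(records, planned, rois)
        assert table["dd98_pct"].iloc[0] == 0.0
        assert table["ddmean_pct"].iloc[0] == 0.0
        assert info["scale"] == 1.0

    def test_balanced_random_component_cancels(self):
        planned, rois = self._planned()
        pf = planned.dose * (1.0 / 28)
        records = []
        for k in range(1, 29):
            scale = 1.02 if k % 2 else 0.98
            records.append(
                FractionRecord(k, delivered_dose=DoseGrid(pf * scale, planned.spacing,
                                                          planned.origin))
            )
        acc, table, info = accumulate_rigid(records, planned, rois)
        assert abs(table["dd98_pct"].iloc[0]) < 1e-9
        assert abs(table["ddmean_pct"].iloc[0]) < 1e-9

    def test_excluded_fractions_rescale_by_count(self):
        planned, rois = self._planned()
        pf = planned.dose * (1.0 / 28)
        records = []
        for k in range(1, 29):
            excluded = k <= 6
            records.append(
                FractionRecord(
                    k, excluded=excluded, reason="corrupt" if excluded else "",
                    delivered_dose=None if excluded else DoseGrid(pf, planned.spacing,
                                                                  planned.origin),
                )
            )
        acc, table, info = accumulate_rigid(records, planned, rois)
        assert info["n_included"] == 22
        assert info["scale"] == pytest.approx(28 / 22)
        assert len(info["excluded"]) == 6
        assert abs(table["ddmean_pct"].iloc[0]) < 1e-9  # rescaling restores the course total

    def test_all_excluded_rejected(self):
        planned, rois = self._planned()
        records = [FractionRecord(1, excluded=True, reason="x")]
        with pytest.raises(EmptyCourseError):
            accumulate_rigid(records, planned, rois)

    def test_accumulation_linearity(self):
        planned, rois = self._planned()
        pf = planned.dose * (1.0 / 4)
        recs = [
            FractionRecord(k, delivered_dose=DoseGrid(pf * (1 + 0.01 * k), planned.spacing,
                                                      planned.origin))
            for k in range(1, 5)
        ]
        scaled = [
            FractionRecord(r.fraction_index,
                           delivered_dose=DoseGrid(r.delivered_dose.dose * 3.0,
                                                   planned.spacing, planned.origin))
            for r in recs
        ]
        acc1, _, _ = accumulate_rigid(recs, planned)
        acc3, _, _ = accumulate_rigid(scaled, planned)
        assert np.allclose(acc3.dose, 3.0 * acc1.dose, rtol=1e-12)


class TestDice:
    def _cube(self, lo, name="a"):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[lo[0] : lo[0] + 10, lo[1] : lo[1] + 10, lo[2] : lo[2] + 10] = True
        return StructureMask(name, mask, (1, 1, 1), (0, 0, 0))

    def test_identical_masks(self):
        a = self._cube((5, 5, 5))
        assert dice_coefficient(a, a) == 1.0

    def test_disjoint_masks(self):
        mask_b = np.zeros((20, 20, 20), dtype=bool)
        mask_b[0:2, 0:2, 0:2] = True
        b = StructureMask("b", mask_b, (1, 1, 1), (0, 0, 0))
        assert dice_coefficient(self._cube((10, 10, 10)), b) == 0.0

    def test_half_shifted_cube(self):
        a = self._cube((5, 5, 5))
        b = self._cube((10, 5, 5), "b")
        assert dice_coefficient(a, b) == 0.5

    def test_symmetry_and_range(self, rng):
        a = StructureMask("a", rng.uniform(size=(10, 10, 10)) > 0.5, (1, 1, 1), (0, 0, 0))
        b = StructureMask("b", rng.uniform(size=(10, 10, 10)) > 0.5, (1, 1, 1), (0, 0, 0))
        assert dice_coefficient(a, b) == dice_coefficient(b, a)
        assert 0.0 <= dice_coefficient(a, b) <= 1.0

    def test_both_empty_rejected(self):
        empty = StructureMask("e", np.zeros((4, 4, 4), dtype=bool), (1, 1, 1), (0, 0, 0))
        with pytest.raises(DegenerateROIError):
            dice_coefficient(empty, empty)


class TestApplyDeformation:
    def _linear_dose(self):
        shape = (16, 16, 16)
        ax = [np.arange(s) * 2.0 for s in shape]
        dose = (
            10.0 + 0.5 * ax[0][:, None, None] + 0.3 * ax[1][None, :, None]
            + 0.2 * ax[2][None, None, :]
        )
        return DoseGrid(dose, (2, 2, 2), (0, 0, 0))

    def test_zero_field_is_identity(self):
        dose = self._linear_dose()
        dvf = DeformationField(np.zeros(dose.shape + (3,)), dose.spacing, dose.origin)
        out = apply_deformation(dose, dvf)
        assert np.allclose(out.dose, dose.dose, atol=1e-12)

    def test_constant_one_voxel_displacement_matches_shift(self):
        dose = self._linear_dose()
        disp = np.zeros(dose.shape + (3,))
        disp[..., 0] = 2.0  # one voxel along +x
        out = apply_deformation(dose, DeformationField(disp, dose.spacing, dose.origin))
        # pull-back reads one voxel further along x; last column maps outside
        assert np.allclose(out.dose[:-1], dose.dose[1:], atol=1e-12)

    def test_linear_field_matches_analytic_composition(self, rng):
        """Trilinear interpolation is exact on a linear dose: the warped dose
        equals the closed-form evaluation of dose(x + u(x)) wherever the
        displaced position stays inside the grid."""
        dose = self._linear_dose()
        disp = rng.uniform(-3.0, 3.0, dose.shape + (3,))
        out = apply_deformation(dose, DeformationField(disp, dose.spacing, dose.origin))
        ax = [np.arange(s) * 2.0 for s in dose.shape]
        xs, ys, zs = np.meshgrid(*ax, indexing="ij")
        px, py, pz = xs + disp[..., 0], ys + disp[..., 1], zs + disp[..., 2]
        inside = (
            (px >= 0) & (px <= 30) & (py >= 0) & (py <= 30) & (pz >= 0) & (pz <= 30)
        )
        analytic = 10.0 + 0.5 * px + 0.3 * py + 0.2 * pz
        assert np.allclose(out.dose[inside], analytic[inside], atol=1e-9)

    def test_grid_mismatch_rejected(self):
        dose = self._linear_dose()
        dvf = DeformationField(np.zeros((8, 8, 8, 3)), dose.spacing, dose.origin)
        with pytest.raises(FrameError):
            apply_deformation(dose, dvf)


class TestPairedTest:
    def test_identical_pairs_degenerate(self):
        res = paired_comparison_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and not res.significant

    def test_constant_difference_degenerate(self):
        res = paired_comparison_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.degenerate
        assert res.mean_diff == -1.0

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(50.0, 2.0, 13)
        b = a + rng.normal(0.5, 1.0, 13)
        res = paired_comparison_test(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(13))
        p = 2 * sps.t.sf(abs(t), 12)
        assert res.t_statistic == pytest.approx(t, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            paired_comparison_test([1.0], [2.0])


class TestBeamModel:
    def test_equispaced_weights_sum_to_one(self):
        beams = BeamModel.equispaced(9)
        assert beams.weights.sum() == pytest.approx(1.0)
        assert len(beams.gantry_angles_deg) == 9

    def test_source_position_at_sad(self):
        beams = BeamModel.equispaced(7)
        src = beams.source_position(0, (0, 0, 0))
        assert np.allclose(src, [0, 1000, 0])  # gantry 0: anterior source
        assert np.linalg.norm(src) == pytest.approx(beams.sad_mm)
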