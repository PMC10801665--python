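"""Dose-engine tests: inverse-square closed forms, superposition, the
loop-written formula oracle, DVH voxel-sort oracles, and plan comparison."""

import numpy as np
import pytest

import hdrneedle as hn
from hdrneedle.digitize import DwellSet
from hdrneedle.dose import MIN_RADIUS_MM, _CGY_H_TO_GY_S


def single_dwell_plan(src, pos=(0.0, 0.0, 0.0), time_s=3600.0 * 100.0):
    d = DwellSet(0, np.asarray([pos]), np.asarray([time_s]), 2.5, 0.0)
    return hn.Plan([d], src)


def oracle_dose(point, plan):
    """Independent loop transcription of the TG-43 point-source sum."""
    total = 0.0
    src = plan.source
    for needle in plan.needles:
        for pos, t in zip(needle.positions, needle.times):
            r = float(np.sqrt(sum((a - b) ** 2 for a, b in zip(point, pos))))
            r = max(r, MIN_RADIUS_MM)
            g = np.interp(r, src.radial_dose[:, 0], src.radial_dose[:, 1])
            phi = np.interp(r, src.anisotropy[:, 0], src.anisotropy[:, 1])
            rate = (src.air_kerma_strength * src.dose_rate_constant
                    * (src.reference_r0 / r) ** 2 * g * phi)
            total += rate * t * _CGY_H_TO_GY_S
    return total


class TestSourceModel:
    def test_non_increasing_radii_rejected(self):
        tab = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="increasing"):
            hn.SourceModel(1.0, 1.0, tab, tab)

    def test_radial_dose_must_be_normalized_at_r0(self):
        tab = np.array([[1.0, 2.0], [100.0, 2.0]])
        good = np.array([[1.0, 1.0], [100.0, 1.0]])
        with pytest.raises(ValueError, match="r0"):
            hn.SourceModel(1.0, 1.0, tab, good)

    def test_bundled_generic_source_loads(self):
        src = hn.SourceModel.generic_ir192()
        assert src.dose_rate_constant == pytest.approx(1.109)
        assert src.reference_r0 == 10.0
        assert np.interp(10.0, src.radial_dose[:, 0], src.radial_dose[:, 1]) == 1.0


class TestDoseAtPoint:
    def test_inverse_square_law_with_unity_tables(self):
        src = hn.SourceModel.unity()
        # choose the dwell time so the dose at r0 is exactly 1 Gy
        t = 3600.0 * 100.0 / (src.air_kerma_strength * src.dose_rate_constant)
        plan = single_dwell_plan(src, time_s=t)
        d_r0 = hn.dose_at_point((10.0, 0.0, 0.0), plan)
        d_2r0 = hn.dose_at_point((20.0, 0.0, 0.0), plan)
        assert d_r0 == pytest.approx(1.0, rel=1e-10)
        assert d_2r0 / d_r0 == pytest.approx(0.25, rel=1e-10)

    def test_dose_times_r_squared_constant_along_ray(self):
        src = hn.SourceModel.unity()
        plan = single_dwell_plan(src)
        direction = np.array([1.0, 2.0, 2.0]) / 3.0
        values = []
        for r in np.linspace(5, 500, 10):
            d = hn.dose_at_point(tuple(r * direction), plan)
            values.append(d * r ** 2)
        assert np.ptp(values) / values[0] < 1e-10

    def test_superposition_of_two_dwells(self):
        src = hn.SourceModel.unity()
        d1 = DwellSet(0, [[0, 0, 0]], [100.0], 2.5, 0)
        d2 = DwellSet(1, [[30, 0, 0]], [250.0], 2.5, 0)
        p12 = hn.Plan([d1, d2], src)
        p1 = hn.Plan([d1], src)
        p2 = hn.Plan([d2], src)
        pt = (11.0, 7.0, -3.0)
        assert hn.dose_at_point(pt, p12) == pytest.approx(
            hn.dose_at_point(pt, p1) + hn.dose_at_point(pt, p2), rel=1e-12)

    def test_matches_independent_loop_oracle(self, rng):
        src = hn.SourceModel.generic_ir192()
        needles = []
        for i in range(3):
            pos = rng.uniform(10, 40, size=(4, 3))
            times = rng.uniform(1, 30, size=4)
            needles.append(DwellSet(i, pos, times, 2.5, 0))
        plan = hn.Plan(needles, src)
        for _ in range(10):
            pt = tuple(rng.uniform(0, 50, 3))
            assert hn.dose_at_point(pt, plan, allow_extrapolation=True) == \
                pytest.approx(oracle_dose(pt, plan), rel=1e-10)

    def test_out_of_table_range_raises_without_extrapolation(self):
        src = hn.SourceModel.generic_ir192()
        plan = single_dwell_plan(src)
        with pytest.raises(ValueError, match="extrapolation"):
            hn.dose_at_point((500.0, 0, 0), plan)

    def test_near_source_clamp_warns(self):
        src = hn.SourceModel.unity()
        plan = single_dwell_plan(src)
        with pytest.warns(UserWarning, match="clamped"):
            d = hn.dose_at_point((0.1, 0.0, 0.0), plan)
        assert np.isfinite(d)


class TestDoseGrid:
    def test_zero_dwell_times_give_zero_grid(self):
        src = hn.SourceModel.unity()
        d = DwellSet(0, [[10, 10, 10]], [0.0], 2.5, 0)
        grid = hn.Volume(np.zeros((8, 8, 8)), (2, 2, 2))
        out = hn.dose_grid(grid, hn.Plan([d], src))
        assert np.all(out.data == 0)

    def test_translation_equivariance(self):
        src = hn.SourceModel.unity()
        d0 = DwellSet(0, [[8, 8, 8]], [50.0], 2.5, 0)
        grid0 = hn.Volume(np.zeros((8, 8, 8)), (2, 2, 2), (0, 0, 0))
        delta = np.array([5.0, -3.0, 2.0])
        d1 = DwellSet(0, [np.array([8, 8, 8]) + delta], [50.0], 2.5, 0)
        grid1 = hn.Volume(np.zeros((8, 8, 8)), (2, 2, 2), tuple(delta))
        out0 = hn.dose_grid(grid0, hn.Plan([d0], src))
        out1 = hn.dose_grid(grid1, hn.Plan([d1], src))
        assert np.allclose(out0.data, out1.data, rtol=1e-12)

    def test_hottest_voxel_is_adjacent_to_a_dwell(self, default_phantom):
        vol, truth = default_phantom
        src = hn.SourceModel.generic_ir192()
        needles = [hn.sample_dwells(t, 2.5, 0.0, 5, 10.0, i)
                   for i, t in enumerate(truth.centerlines)]
        plan = hn.Plan(needles, src)
        dose = hn.dose_grid(vol, plan)
        argmax = np.unravel_index(np.argmax(dose.data), dose.data.shape)
        world = np.asarray(vol.origin) + np.asarray(argmax) * np.asarray(vol.spacing)
        pos, _ = plan.all_dwells()
        nearest = np.linalg.norm(pos - world, axis=1).min()
        assert nearest <= np.linalg.norm(vol.spacing)

    def test_values_finite_and_nonnegative(self, small_phantom):
        vol, truth = small_phantom
        src = hn.SourceModel.generic_ir192()
        needles = [hn.sample_dwells(t, 2.5, 0.0, 3, 10.0, i)
                   for i, t in enumerate(truth.centerlines)]
        dose = hn.dose_grid(vol, hn.Plan(needles, src))
        assert np.all(np.isfinite(dose.data)) and np.all(dose.data >= 0)


class TestDVH:
    def _uniform_case(self, value=4.0):
        dose = hn.Volume(np.full((10, 10, 10), value), (2.0, 2.0, 2.0))
        struct = hn.Volume(np.ones((10, 10, 10), np.uint8), (2.0, 2.0, 2.0))
        return dose, struct

    def test_uniform_dose_collapses_all_metrics(self):
        dose, struct = self._uniform_case(4.0)
        dvh = hn.compute_dvh(dose, struct)
        assert dvh.d90 == pytest.approx(4.0, abs=0.011)
        assert dvh.d100 == pytest.approx(4.0)
        assert dvh.structure_volume_cc == pytest.approx(8.0)

    def test_half_hot_half_cold_structure(self):
        data = np.zeros((10, 10, 10))
        data[:5] = 10.0
        dose = hn.Volume(data, (2.0, 2.0, 2.0))
        struct = hn.Volume(np.ones_like(data, dtype=np.uint8), (2.0, 2.0, 2.0))
        dvh = hn.compute_dvh(dose, struct)
        assert dvh.d90 == pytest.approx(0.0, abs=0.011)
        assert dvh.d100 == pytest.approx(0.0)

    def test_d90_matches_voxel_sort_oracle(self, rng):
        for _ in range(10):
            data = rng.gamma(2.0, 2.0, size=(12, 12, 6))
            sel = rng.random((12, 12, 6)) < 0.5
            sel[0, 0, 0] = True
            dose = hn.Volume(data, (2.0, 2.0, 5.0))
            struct = hn.Volume(sel.astype(np.uint8), (2.0, 2.0, 5.0))
            dvh = hn.compute_dvh(dose, struct, bin_width_gy=0.01)
            doses = np.sort(data[sel])[::-1]
            k = int(np.ceil(0.9 * doses.size)) - 1
            assert abs(dvh.d90 - doses[k]) <= 0.011

    def test_d100_never_exceeds_d90(self, rng):
        for _ in range(20):
            data = rng.exponential(3.0, size=(8, 8, 8))
            sel = rng.random((8, 8, 8)) < 0.4
            sel[0, 0, 0] = True
            dvh = hn.compute_dvh(hn.Volume(data, (2, 2, 2)),
                                 hn.Volume(sel.astype(np.uint8), (2, 2, 2)))
            assert dvh.d100 <= dvh.d90 + 1e-9

    def test_cumulative_curve_starts_at_one_and_decreases(self, rng):
        data = rng.random((8, 8, 8)) * 5
        dvh = hn.compute_dvh(hn.Volume(data, (2, 2, 2)),
                             hn.Volume(np.ones((8, 8, 8), np.uint8), (2, 2, 2)))
        assert dvh.cumulative_volume[0] == pytest.approx(1.0)
        assert np.all(np.diff(dvh.cumulative_volume) <= 1e-12)

    def test_d2cc_for_known_hot_fraction(self):
        # 1000 voxels of 8 mm^3 = 8 cc; hottest 2 cc = 250 voxels
        data = np.arange(1000, dtype=float).reshape(10, 10, 10) / 100.0
        dose = hn.Volume(data, (2.0, 2.0, 2.0))
        struct = hn.Volume(np.ones((10, 10, 10), np.uint8), (2.0, 2.0, 2.0))
        dvh = hn.compute_dvh(dose, struct)
        assert dvh.d2cc == pytest.approx(7.5, abs=0.02)

    def test_small_structure_reports_d2cc_undefined(self):
        dose = hn.Volume(np.full((4, 4, 4), 2.0), (1, 1, 1))
        struct = hn.Volume(np.ones((4, 4, 4), np.uint8), (1, 1, 1))
        with pytest.warns(UserWarning, match="2 cc"):
            dvh = hn.compute_dvh(dose, struct)
        assert dvh.d2cc is None

    def test_empty_structure_raises(self):
        dose = hn.Volume(np.ones((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            hn.compute_dvh(dose, hn.Volume(np.zeros((4, 4, 4), np.uint8), (1, 1, 1)))


class TestDoseDifference:
    def test_identical_plans_give_zero(self):
        assert hn.dose_difference(6.0, 6.0) == (0.0, 0.0)

    def test_hand_value(self):
        diff, rel = hn.dose_difference(6.0, 5.9)
        assert diff == pytest.approx(0.1)
        assert rel == pytest.approx(0.1 / 6.0, abs=1e-9)

    def test_swapping_arguments_negates_both(self):
        d1, r1 = hn.dose_difference(6.0, 5.0)
        d2, r2 = hn.dose_difference(5.0, 6.0)
        assert d1 == -d2
        # the relative form negates its numerator (its denominator is the
        # first argument by definition)
        assert r1 * 6.0 == pytest.approx(-r2 * 5.0)
        assert (r1 > 0) and (r2 < 0)

    def test_zero_manual_metric_raises_for_relative(self):
        with pytest.raises(ValueError, match="manual"):
            hn.dose_difference(0.0, 1.0)
        assert hn.dose_difference(0.0, 1.0, relative=False) == (-1.0, None)
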