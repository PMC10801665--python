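"""Digitization tests: instance labeling, centerline extraction, polynomial
fitting, dwell placement, and needle matching."""


import numpy as np
import pytest

import hdrneedle as hn
from hdrneedle.digitize import trajectory_from_polynomial

from conftest import straight_tube_mask


class TestLabelNeedles:
    def test_two_disjoint_tubes_give_two_instances(self):
        m1 = straight_tube_mask(center=(4, 4)).data
        m2 = straight_tube_mask(center=(12, 12)).data
        mask = hn.Volume(((m1 + m2) > 0).astype(np.uint8), (1, 1, 1))
        labeled, k = hn.label_needles(mask)
        assert k == 2
        assert set(np.unique(labeled.data)) == {0, 1, 2}

    def test_empty_mask_warns_and_returns_zero(self):
        mask = hn.Volume(np.zeros((8, 8, 4), dtype=np.uint8), (1, 1, 1))
        with pytest.warns(UserWarning, match="empty"):
            _, k = hn.label_needles(mask)
        assert k == 0

    def test_small_components_discarded_as_noise(self):
        data = straight_tube_mask(center=(4, 4)).data.copy()
        data[15, 15, 0] = 1  # single-voxel speck
        _, k = hn.label_needles(hn.Volume(data, (1, 1, 1)), min_voxels=5)
        assert k == 1

    def test_phantom_instances_recovered_up_to_permutation(self, default_phantom):
        _, truth = default_phantom
        labeled, k = hn.label_needles(truth.binary_mask)
        assert k == 4
        # each recovered component coincides with exactly one GT instance
        for lab in range(1, k + 1):
            sel = labeled.data == lab
            gt_labels = np.unique(truth.instance_mask.data[sel])
            assert len(gt_labels) == 1


class TestExtractCenterline:
    def test_vertical_tube_centroids_are_exact(self):
        mask = straight_tube_mask(center=(8, 8))
        pts, merged = hn.extract_centerline(mask, 1)
        assert not merged
        assert np.allclose(pts[:, 0], 8.0)
        assert np.allclose(pts[:, 1], 8.0)
        assert np.array_equal(pts[:, 2], np.arange(8, dtype=float))

    def test_phantom_centroids_follow_analytic_curve(self, default_phantom):
        _, truth = default_phantom
        sx = truth.instance_mask.spacing[0]
        for label, traj in enumerate(truth.centerlines, start=1):
            pts, merged = hn.extract_centerline(truth.instance_mask, label)
            assert not merged
            xy = traj.xy_at(pts[:, 2])
            err = np.hypot(pts[:, 0] - xy[:, 0], pts[:, 1] - xy[:, 1])
            assert err.max() < 0.5 * sx

    def test_merged_tubes_are_flagged(self):
        # one component that follows needle A on low slices, then widens to
        # include needle B (entering mid-volume, bridged at slice 4): the
        # centroid jumps by ~5 mm, far above 2x the needle diameter
        shape = (24, 24, 10)
        data = np.zeros(shape, dtype=np.uint8)
        a = straight_tube_mask(shape, center=(6, 12), z_slices=range(10)).data
        b = straight_tube_mask(shape, center=(16, 12), z_slices=range(4, 10)).data
        data[(a + b) > 0] = 1
        data[6:17, 12, 4] = 1  # bridge connecting A and B on slice 4
        with pytest.warns(UserWarning, match="merged|touching"):
            pts, merged = hn.extract_centerline(hn.Volume(data, (1, 1, 1)), 1)
        assert merged

    def test_single_slice_instance_rejected(self):
        mask = straight_tube_mask(z_slices=[3])
        with pytest.raises(ValueError, match="slice"):
            hn.extract_centerline(mask, 1)


class TestFitTrajectory:
    def test_exact_reproduction_of_low_degree_curve(self):
        z = np.arange(10, dtype=float)
        x = 1.0 + 0.2 * z + 0.01 * z ** 2
        y = 2.0 - 0.1 * z
        traj = hn.fit_trajectory(np.stack([x, y, z], axis=1), degree=3)
        assert np.abs(traj.points[:, 0] - x).max() < 1e-9
        assert np.abs(traj.points[:, 1] - y).max() < 1e-9

    def test_straight_needle_arc_length(self):
        z = np.linspace(0, 50, 11)
        pts = np.stack([np.full_like(z, 3.0), np.full_like(z, 4.0), z], axis=1)
        traj = hn.fit_trajectory(pts, degree=3)
        assert traj.length_mm == pytest.approx(50.0, abs=1e-6)
        assert traj.tip == pytest.approx((3.0, 4.0, 50.0))

    def test_fit_smooths_noisy_centroids(self, rng):
        z = np.arange(16, dtype=float) * 5.0
        true_x = 10 + 0.05 * z + 2e-4 * z ** 2
        true_y = 20 - 0.04 * z
        rms_raw, rms_fit = [], []
        for _ in range(100):
            nx = true_x + rng.normal(0, 0.3, z.size)
            ny = true_y + rng.normal(0, 0.3, z.size)
            traj = hn.fit_trajectory(np.stack([nx, ny, z], axis=1), degree=3)
            rms_raw.append(np.sqrt(np.mean((nx - true_x) ** 2 + (ny - true_y) ** 2)))
            fit = traj.points
            rms_fit.append(np.sqrt(np.mean((fit[:, 0] - true_x) ** 2
                                           + (fit[:, 1] - true_y) ** 2)))
        assert np.mean(rms_fit) < np.mean(rms_raw)

    def test_refit_is_idempotent(self, rng):
        z = np.arange(12, dtype=float)
        pts = np.stack([rng.normal(10, 1, 12), rng.normal(10, 1, 12), z], axis=1)
        t1 = hn.fit_trajectory(pts, degree=3)
        t2 = hn.fit_trajectory(t1.points, degree=3)
        assert np.abs(t1.poly_x - t2.poly_x).max() < 1e-9
        assert np.abs(t1.poly_y - t2.poly_y).max() < 1e-9

    def test_tip_extrapolation_extends_beyond_last_slice(self):
        z = np.arange(8, dtype=float) * 5.0
        pts = np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=1)
        traj = hn.fit_trajectory(pts, degree=1, tip_extrapolation_mm=2.5)
        assert traj.tip[2] == pytest.approx(37.5)
        assert traj.length_mm == pytest.approx(37.5, abs=1e-6)

    def test_single_slice_points_raise(self):
        pts = np.array([[0, 0, 5.0], [1, 0, 5.0]])
        with pytest.raises(ValueError):
            hn.fit_trajectory(pts)


class TestSampleDwells:
    def _straight(self, z_tip=100.0):
        return trajectory_from_polynomial([0.0], [0.0], 0.0, z_tip)

    def test_straight_needle_dwell_arithmetic(self):
        d = hn.sample_dwells(self._straight(), step_mm=2.5, offset_mm=0.0, n_dwells=3)
        assert np.allclose(d.positions[:, 2], [100.0, 97.5, 95.0], atol=1e-6)
        assert np.allclose(d.positions[:, :2], 0.0, atol=1e-9)

    def test_single_dwell_sits_at_tip(self):
        d = hn.sample_dwells(self._straight(), 2.5, 0.0, 1)
        assert np.allclose(d.positions[0], [0, 0, 100.0], atol=1e-6)

    def test_curved_needle_arc_separation_within_tolerance(self, default_phantom):
        _, truth = default_phantom
        for traj in truth.centerlines:
            d = hn.sample_dwells(traj, step_mm=2.5, offset_mm=0.0, n_dwells=8)
            # recompute arc separations by fine quadrature between dwells
            z, s = traj.arc_table(n=20001)
            s_at = np.interp(d.positions[:, 2], z, s)
            seps = -np.diff(s_at)
            assert np.all(np.abs(seps - 2.5) < 0.025)

    def test_positions_lie_on_fitted_curve(self, default_phantom):
        _, truth = default_phantom
        traj = truth.centerlines[0]
        d = hn.sample_dwells(traj, 2.5, 1.0, 6)
        resid = np.linalg.norm(d.positions[:, :2] - traj.xy_at(d.positions[:, 2]),
                               axis=1)
        assert resid.max() < 0.1

    def test_too_many_dwells_raise_with_needle_name(self):
        with pytest.raises(ValueError, match="needle 3"):
            hn.sample_dwells(self._straight(z_tip=10.0), 2.5, 0.0, 50, needle_id=3)


class TestMatchNeedles:
    def _trajs(self, offsets):
        return [trajectory_from_polynomial([10.0 * i + dx], [5.0 + dy], 0.0, 50.0)
                for i, (dx, dy) in enumerate(offsets)]

    def test_identity_pairing(self):
        t = self._trajs([(0, 0)] * 3)
        tt = self._trajs([(0, 0)] * 3)
        pairs, fp, fn = hn.match_needles(t, tt)
        assert len(pairs) == 3 and not fp and not fn

    def test_reversed_lists_recover_permutation(self):
        truth = self._trajs([(0, 0), (0, 0), (0, 0), (0, 0)])
        pred = list(reversed(truth))
        pairs, _, _ = hn.match_needles(pred, truth)
        assert sorted(pairs) == [(0, 3), (1, 2), (2, 1), (3, 0)]

    def test_jittered_needles_always_pair_correctly(self, rng):
        for _ in range(100):
            truth = self._trajs([(0, 0)] * 4)  # 10 mm apart in x
            jitter = rng.uniform(-0.5, 0.5, size=(4, 2))
            pred = self._trajs([(jx, jy) for jx, jy in jitter])
            pairs, fp, fn = hn.match_needles(pred, truth)
            assert pairs == [(i, i) for i in range(4)] and not fp and not fn

    def test_extra_prediction_reported_as_false_positive(self):
        truth = self._trajs([(0, 0)] * 2)
        pred = self._trajs([(0, 0)] * 3)
        pairs, fp, fn = hn.match_needles(pred, truth)
        assert len(pairs) == 2 and len(fp) == 1 and not fn


class TestEndToEnd:
    def test_ground_truth_mask_digitization_recovers_geometry(self, default_phantom):
        """Digitizing the noise-free GT mask: tip error within half a slice,
        shaft error within one in-plane voxel."""
        _, truth = default_phantom
        trajs = hn.digitize_mask(truth.binary_mask)
        assert len(trajs) == 4
        pairs_idx, fp, fn = hn.match_needles(trajs, truth.centerlines)
        assert not fp and not fn
        pairs = [(trajs[i], truth.centerlines[j]) for i, j in pairs_idx]
        tip_err, _ = hn.tip_error(pairs)
        assert tip_err <= 2.5
        assert hn.shaft_error(pairs) <= 0.8

    def test_dwells_translate_rigidly_with_the_volume(self, small_phantom):
        _, truth = small_phantom
        mask = truth.binary_mask
        delta = np.array([7.0, -3.0, 12.0])
        shifted = hn.Volume(mask.data.copy(), mask.spacing,
                            tuple(np.asarray(mask.origin) + delta))
        t0 = hn.digitize_mask(mask)
        t1 = hn.digitize_mask(shifted)
        for a, b in zip(t0, t1):
            d0 = hn.sample_dwells(a, 2.0, 0.0, 4)
            d1 = hn.sample_dwells(b, 2.0, 0.0, 4)
            assert np.allclose(d1.positions, d0.positions + delta, atol=1e-6)
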