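import math
import warnings

import numpy as np
import pytest

import phylomorph as pm
from phylomorph.matrices import FeatureMatrix
from phylomorph.morphometrics import BranchMeasures
from phylomorph.synthetic import ColonyBlueprint, ColonySegment

from conftest import make_y_blueprint

PAPER_SPACING = (0.33, 0.33, 1.50)


def _cylinder(radius=3.0, length=40.0):
    return ColonyBlueprint("cyl", [
        ColonySegment(np.zeros(3), np.array([0.0, length, 0.0]), radius, None, 0)])


class TestSkeletonize:
    def test_cylinder_single_branch_with_correct_interior_radius(self):
        vol = pm.rasterize(_cylinder(3.0, 40.0), PAPER_SPACING)
        skel = pm.skeletonize(vol)
        assert len(skel.branches) == 1
        assert skel.n_junctions == 0
        br = skel.branches[0]
        s = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(br.centerline, axis=0), axis=1))])
        interior = (s > 6.0) & (s < s[-1] - 6.0)
        pitch = max(PAPER_SPACING)
        assert np.all(np.abs(br.radii[interior] - 3.0) <= pitch)

    def test_y_blueprint_one_junction_three_branches(self):
        vol = pm.rasterize(make_y_blueprint(30.0), (0.5, 0.5, 0.5))
        skel = pm.skeletonize(vol)
        assert skel.n_junctions == 1
        assert len(skel.branches) == 3
        kinds = sorted(n.kind for n in skel.nodes)
        assert kinds == ["basal", "junction", "tip", "tip"]

    def test_sphere_prunes_to_nothing_with_warning(self):
        sphere = ColonyBlueprint("s", [
            ColonySegment(np.zeros(3), np.zeros(3), 8.0, None, 0)])
        vol = pm.rasterize(sphere, (1, 1, 1))
        with pytest.warns(UserWarning, match="degenerate|no branches"):
            skel = pm.skeletonize(vol)
        assert len(skel.branches) == 0

    def test_empty_volume_errors(self):
        vol = pm.VoxelVolume(np.zeros((5, 5, 5), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="no foreground"):
            pm.skeletonize(vol)


class TestInscribedDiameter:
    def test_sphere_center_diameter(self):
        sphere = ColonyBlueprint("s", [
            ColonySegment(np.zeros(3), np.zeros(3), 10.0, None, 0)])
        vol = pm.rasterize(sphere, PAPER_SPACING)
        d = pm.inscribed_diameter(vol, (0.0, 0.0, 0.0))
        assert abs(d - 20.0) <= max(PAPER_SPACING)
        # brute-force oracle: distance from center voxel to nearest background
        idx = vol.mm_to_voxel(np.zeros(3))
        bg = np.argwhere(~vol.occupancy)
        gaps = (bg - idx) * np.asarray(vol.spacing)
        assert d == pytest.approx(2 * np.min(np.linalg.norm(gaps, axis=1)), rel=1e-9)

    def test_boundary_voxel_small_diameter(self):
        sphere = ColonyBlueprint("s", [
            ColonySegment(np.zeros(3), np.zeros(3), 5.0, None, 0)])
        vol = pm.rasterize(sphere, (1, 1, 1))
        # step outwards along +x until the last foreground voxel
        idx = vol.mm_to_voxel(np.zeros(3))
        x = idx[0]
        while vol.occupancy[x + 1, idx[1], idx[2]]:
            x += 1
        point = vol.voxel_to_mm(np.array([x, idx[1], idx[2]]))
        assert pm.inscribed_diameter(vol, point) <= 2.0 + 1e-9

    def test_origin_invariance(self):
        sphere = ColonyBlueprint("s", [
            ColonySegment(np.zeros(3), np.zeros(3), 6.0, None, 0)])
        vol = pm.rasterize(sphere, (1, 1, 1))
        shifted = pm.VoxelVolume(vol.occupancy, vol.spacing,
                                 tuple(np.asarray(vol.origin) + [5.0, -3.0, 2.0]))
        d1 = pm.inscribed_diameter(vol, (0, 0, 0))
        d2 = pm.inscribed_diameter(shifted, (5.0, -3.0, 2.0))
        assert d1 == pytest.approx(d2)

    def test_background_point_errors(self):
        sphere = ColonyBlueprint("s", [
            ColonySegment(np.zeros(3), np.zeros(3), 3.0, None, 0)])
        vol = pm.rasterize(sphere, (1, 1, 1))
        with pytest.raises(ValueError, match="background"):
            pm.inscribed_diameter(vol, (0.0, 5.5, 0.0))


class TestMeasureBranches:
    def test_y_bifurcation_angle_recovered(self):
        vol = pm.rasterize(make_y_blueprint(30.0), (0.5, 0.5, 0.5))
        measures = pm.measure_branches(pm.skeletonize(vol))
        tip_angles = [m.b_angle for m in measures if m.is_tip and math.isfinite(m.b_angle)]
        assert len(tip_angles) == 2
        for angle in tip_angles:
            assert angle == pytest.approx(60.0, abs=10.0)

    def test_vertical_cylinder_g_angle_zero(self):
        vol = pm.rasterize(_cylinder(3.0, 40.0), PAPER_SPACING)
        measures = pm.measure_branches(pm.skeletonize(vol))
        assert len(measures) == 1
        assert measures[0].g_angle == pytest.approx(0.0, abs=3.0)

    def test_parallel_branch_spacing_recovered(self):
        # two parallel verticals 12 mm apart; tip-to-nearest-centerline = 12
        r, sep, up = 1.5, 12.0, 25.0
        top = np.array([0.0, 12.0, 0.0])
        segs = [ColonySegment(np.zeros(3), top, r, None, 0)]
        for sign in (+1, -1):
            arm_end = top + np.array([sign * sep / 2, 2.0, 0.0])
            segs.append(ColonySegment(top.copy(), arm_end, r, 0, 1))
            segs.append(ColonySegment(arm_end, arm_end + np.array([0.0, up, 0.0]), r,
                                      len(segs) - 1, 2))
        bp = ColonyBlueprint("H", segs)
        for tip in bp.tip_segments():
            assert bp.true_tip_spacing(tip) == pytest.approx(sep)
        vol = pm.rasterize(bp, (0.5, 0.5, 0.5))
        measures = pm.measure_branches(pm.skeletonize(vol))
        spacings = [m.br_spacing for m in measures if m.is_tip and m.g_angle < 30]
        assert len(spacings) == 2
        for s in spacings:
            assert abs(s - sep) <= 1.0  # within ~one voxel pitch plus jaggedness

    def test_bifurcation_count_matches_blueprint(self, colony_bundle):
        assert colony_bundle["skeleton"].n_junctions == colony_bundle["blueprint"].n_bifurcations

    def test_b_angles_match_blueprint_truth(self, colony_bundle):
        true_angles = sorted(colony_bundle["blueprint"].true_b_angles.values())
        measured = sorted({round(m.b_angle, 6) for m in colony_bundle["measures"]
                           if math.isfinite(m.b_angle)})
        assert len(measured) == len(true_angles)
        for t, m in zip(true_angles, sorted(measured)):
            assert m == pytest.approx(t, abs=12.0)


def _mk(branch_id=0, da=4.0, db=4.0, dc=4.0, b_angle=45.0, g_angle=10.0, rb=20.0,
        br_spacing=8.0, rep=4.0, is_tip=True):
    return BranchMeasures(branch_id, da, db, dc, b_angle, g_angle, rb, br_spacing,
                          rep, is_tip)


class TestAggregateFeatures:
    def test_single_branch_ratio(self):
        cf = pm.aggregate_features([_mk(rep=4.0, rb=20.0)], "c")
        assert cf.length_thickness_ratio == pytest.approx(5.0)
        assert cf.thickness == pytest.approx(4.0)

    def test_identical_branches_equal_per_branch_values(self):
        cf = pm.aggregate_features([_mk(branch_id=i) for i in range(4)], "c")
        assert cf.thickness == pytest.approx(4.0)
        assert cf.spacing == pytest.approx(8.0)
        assert cf.length_thickness_ratio == pytest.approx(5.0)

    def test_thickness_recovery_within_15_percent(self, colony_bundle):
        cf = pm.aggregate_features(colony_bundle["measures"], "c")
        true_diam = 2.0 * colony_bundle["blueprint"].mean_radius()
        assert true_diam == pytest.approx(6.0)
        assert abs(cf.thickness - true_diam) / true_diam < 0.15

    def test_no_tips_errors(self):
        with pytest.raises(ValueError, match="spacing"):
            pm.aggregate_features([_mk(is_tip=False, br_spacing=math.nan)], "c")

    def test_diameter_switch(self):
        ms = [_mk(da=10.0, rep=4.0)]
        assert pm.aggregate_features(ms, "c", diameter="da").thickness == 10.0


class TestNormalizeFeatures:
    def test_two_colonies_sample_sd_convention(self):
        f1 = pm.ColonyFeatures("a", 2.0, 5.0, 4.0)
        f2 = pm.ColonyFeatures("b", 4.0, 9.0, 8.0)
        fm = pm.normalize_features([f1, f2])
        np.testing.assert_allclose(fm.values[0], -1 / np.sqrt(2))
        np.testing.assert_allclose(fm.values[1], 1 / np.sqrt(2))

    def test_column_means_zero(self):
        rng = np.random.default_rng(0)
        feats = [pm.ColonyFeatures(f"c{i}", *rng.uniform(1, 10, 3)) for i in range(8)]
        fm = pm.normalize_features(feats)
        np.testing.assert_allclose(fm.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(fm.values.std(axis=0, ddof=1), 1.0, rtol=1e-12)

    def test_identical_colonies_zero_with_warning(self):
        feats = [pm.ColonyFeatures(f"c{i}", 3.0, 6.0, 5.0) for i in range(3)]
        with pytest.warns(UserWarning, match="zero variance"):
            fm = pm.normalize_features(feats)
        np.testing.assert_array_equal(fm.values, 0.0)

    def test_single_colony_errors(self):
        with pytest.raises(ValueError):
            pm.normalize_features([pm.ColonyFeatures("c", 1, 2, 3)])


class TestMorphologicalDistances:
    def test_three_four_five(self):
        fm = FeatureMatrix(["a", "b"], ["t1", "t2", "t3"],
                           np.array([[0, 0, 0], [3, 4, 0.0]]))
        dm = pm.morphological_distances(fm)
        assert dm[("a", "b")] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 3))
        fm = FeatureMatrix([f"c{i}" for i in range(20)], ["t1", "t2", "t3"], X)
        dm = pm.morphological_distances(fm)
        for i in range(20):
            for j in range(20):
                expected = math.sqrt(sum((X[i, k] - X[j, k]) ** 2 for k in range(3)))
                assert dm.values[i, j] == pytest.approx(expected)

    def test_nan_rejected(self):
        fm = FeatureMatrix(["a", "b"], ["t1"], np.array([[1.0], [np.nan]]))
        with pytest.raises(ValueError, match="NaN"):
            pm.morphological_distances(fm)


class TestGeometricInvariances:
    @staticmethod
    def _aggregate(bp, spacing):
        vol = pm.rasterize(bp, spacing)
        return pm.aggregate_features(pm.measure_branches(pm.skeletonize(vol)), "c")

    @staticmethod
    def _transform(bp, fn, scale_r=1.0):
        segs = [ColonySegment(fn(s.start), fn(s.end), s.radius * scale_r, s.parent,
                              s.generation) for s in bp.segments]
        return ColonyBlueprint(bp.species_label, segs, bp.growth_axis, bp.true_b_angles)

    def test_rotation_about_growth_axis(self):
        bp = pm.generate_colony_blueprint(
            dict(mean_radius=2.0, mean_branch_length=20.0, branch_angle=50.0,
                 n_generations=3, angle_jitter=3.0), seed=21)
        rot = self._transform(bp, lambda p: np.array([p[2], p[1], -p[0]]))
        a = self._aggregate(bp, (0.5, 0.5, 0.5))
        b = self._aggregate(rot, (0.5, 0.5, 0.5))
        assert abs(a.thickness - b.thickness) / a.thickness < 0.05
        assert abs(a.spacing - b.spacing) / a.spacing < 0.05

    def test_scale_equivariance(self):
        bp = pm.generate_colony_blueprint(
            dict(mean_radius=2.0, mean_branch_length=20.0, branch_angle=50.0,
                 n_generations=3, angle_jitter=3.0), seed=22)
        k = 1.5
        scaled = self._transform(bp, lambda p: k * p, scale_r=k)
        a = self._aggregate(bp, (0.5, 0.5, 0.5))
        b = self._aggregate(scaled, (0.5, 0.5, 0.5))
        assert b.thickness / a.thickness == pytest.approx(k, rel=0.08)
        assert b.spacing / a.spacing == pytest.approx(k, rel=0.10)
        assert b.length_thickness_ratio == pytest.approx(a.length_thickness_ratio, rel=0.10)
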