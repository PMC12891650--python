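"""Plane placement, slab extraction, side fits and the triangle identity."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from levator_ica.frame import LandmarkSet, build_frame, to_pics_coords
from levator_ica.io import VolumeMask
from levator_ica.measure import (
    GeometryError,
    MeasurementConfig,
    PlaneDefinition,
    compute_plane_ica,
    define_planes,
    extract_slab,
    fit_side_line,
    measure_subject,
    split_sides,
)
from levator_ica.phantom import PhantomSpec, generate_phantom, transform_scene

from conftest import random_rotation


def landmarks_with_span(D: float) -> LandmarkSet:
    return LandmarkSet((0, 0, 0), (0, D + 40, 0), (60, D, 0), (-60, D, 0))


class TestDefinePlanes:
    def test_positions_are_fifths_of_the_span(self):
        ls = landmarks_with_span(80.0)
        planes = define_planes(ls, build_frame(ls), slab_halfwidth=1.0)
        assert [p.axial_position for p in planes] == pytest.approx([16, 32, 48, 64, 80])

    def test_spacing_is_one_fifth(self):
        ls = landmarks_with_span(100.0)
        planes = define_planes(ls, build_frame(ls), slab_halfwidth=1.0)
        diffs = np.diff([p.axial_position for p in planes])
        np.testing.assert_allclose(diffs, 20.0)

    def test_span_is_axial_projection_of_right_spine(self, axis_landmarks):
        planes = define_planes(axis_landmarks, build_frame(axis_landmarks), slab_halfwidth=1.0)
        # IS_R = (-50, 60, -10) projects to 60 on the PICS axis; plane 3 at 36
        assert planes[-1].axial_position == pytest.approx(60.0)
        assert planes[2].axial_position == pytest.approx(36.0)

    def test_anterior_spine_raises_geometry_error(self):
        ls = LandmarkSet((0, 0, 0), (0, 100, 0), (60, -10, 0), (-60, -10, 0))
        with pytest.raises(GeometryError, match="not posterior"):
            define_planes(ls, build_frame(ls), slab_halfwidth=1.0)

    def test_midpoint_scheme_shifts_by_half_a_fifth(self):
        ls = landmarks_with_span(100.0)
        planes = define_planes(ls, build_frame(ls), 1.0, scheme="midpoints")
        assert [p.axial_position for p in planes] == pytest.approx([10, 30, 50, 70, 90])


class TestExtractSlab:
    @given(st.integers(0, 500))
    def test_matches_bruteforce_voxel_filter(self, seed):
        rng = np.random.default_rng(seed)
        voxels = rng.random((12, 14, 10)) < 0.3
        affine = np.eye(4)
        affine[:3, :3] = np.diag(rng.uniform(0.4, 2.0, 3))
        affine[:3, 3] = rng.uniform(-5, 5, 3)
        mask = VolumeMask(voxels=voxels, affine=affine)
        ls = landmarks_with_span(10.0)
        frame = build_frame(ls)
        plane = PlaneDefinition(3, float(rng.uniform(0, 12)), float(rng.uniform(0.5, 3)))

        got = extract_slab(mask, frame, plane)

        expected = []
        for idx in np.argwhere(voxels):
            world = affine[:3, :3] @ idx + affine[:3, 3]
            p = to_pics_coords(world, frame)
            if plane.axial_position - plane.slab_halfwidth <= p[1] < plane.axial_position + plane.slab_halfwidth:
                expected.append(p)
        expected = np.asarray(expected).reshape(-1, 3)
        got_sorted = got[np.lexsort(got.T)] if len(got) else got
        exp_sorted = expected[np.lexsort(expected.T)] if len(expected) else expected
        assert got_sorted.shape == exp_sorted.shape
        np.testing.assert_allclose(got_sorted, exp_sorted, atol=1e-12)

    def test_plane_outside_mask_is_empty(self, symmetric_phantom):
        mask, ls, _ = symmetric_phantom
        frame = build_frame(ls)
        plane = PlaneDefinition(1, 500.0, 1.0)
        assert len(extract_slab(mask, frame, plane)) == 0


class TestSplitSides:
    def test_partition_by_lateral_sign(self):
        pts = np.array([[-3, 0, 0], [-1, 0, 0], [2, 0, 0], [4, 0, 0]], dtype=float)
        left, right = split_sides(pts)
        assert len(left) == 2 and len(right) == 2
        assert (left[:, 0] > 0).all() and (right[:, 0] < 0).all()

    def test_midline_points_discarded(self):
        pts = np.zeros((5, 3))
        left, right = split_sides(pts)
        assert len(left) == 0 and len(right) == 0

    @given(st.integers(0, 500))
    def test_mirroring_swaps_sides_exactly(self, seed):
        pts = np.random.default_rng(seed).uniform(-10, 10, size=(50, 3))
        left, right = split_sides(pts)
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        mleft, mright = split_sides(mirrored)
        np.testing.assert_array_equal(np.sort(mleft[:, 0]), np.sort(-right[:, 0]))
        np.testing.assert_array_equal(np.sort(mright[:, 0]), np.sort(-left[:, 0]))


class TestFitSideLine:
    def test_unit_slope_gives_45_degrees(self):
        pts = np.array([[x, x] for x in np.linspace(1, 5, 20)])
        assert fit_side_line(pts) == pytest.approx(45.0)

    def test_flat_points_give_zero(self):
        pts = np.array([[x, 2.0] for x in np.linspace(1, 5, 20)])
        assert fit_side_line(pts) == pytest.approx(0.0)

    def test_collinear_half_slope(self):
        pts = np.array([[1, 0.5], [2, 1.0], [3, 1.5]])
        assert fit_side_line(pts, min_points=3) == pytest.approx(math.degrees(math.atan(0.5)))
        assert fit_side_line(pts, min_points=3) == pytest.approx(26.565, abs=1e-3)

    def test_negative_slope_reported_as_magnitude(self):
        pts = np.array([[x, -x] for x in np.linspace(1, 5, 20)])
        assert fit_side_line(pts) == pytest.approx(45.0)

    def test_too_few_points_is_unmeasurable(self):
        pts = np.array([[1.0, 1.0], [2.0, 2.0]])
        assert fit_side_line(pts, min_points=10) is None

    def test_zero_lateral_spread_is_unmeasurable(self):
        pts = np.array([[1.0, v] for v in np.linspace(0, 5, 20)])
        assert fit_side_line(pts) is None

    def test_principal_axis_agrees_on_collinear_points(self):
        pts = np.array([[x, 0.7 * x] for x in np.linspace(-3, 3, 25)])
        ols = fit_side_line(pts, estimator="ols")
        pca = fit_side_line(pts, estimator="principal_axis")
        assert ols == pytest.approx(pca, abs=1e-9)


class TestTriangleIdentity:
    @pytest.mark.parametrize(
        "left,right,total",
        [(55.0, 55.0, 70.0), (0.0, 0.0, 180.0), (43.0, 42.0, 95.0), (61.0, 58.0, 61.0)],
    )
    def test_total_is_180_minus_sides(self, left, right, total):
        m = compute_plane_ica(left, right, plane_index=1)
        assert m.total_angle == total and m.measurable

    def test_absent_side_makes_plane_unmeasurable(self):
        m = compute_plane_ica(None, 50.0, plane_index=1)
        assert not m.measurable and m.total_angle is None


class TestMeasureSubject:
    def test_symmetric_phantom_recovers_90_everywhere(self, symmetric_phantom):
        mask, ls, _ = symmetric_phantom
        prof = measure_subject(mask, ls, MeasurementConfig(), subject_id="p45")
        for m in prof.measurements:
            assert m.measurable
            assert m.total_angle == pytest.approx(90.0, abs=2.0)

    def test_total_identity_holds_on_all_outputs(self, varied_phantom):
        mask, ls, _ = varied_phantom
        prof = measure_subject(mask, ls)
        for m in prof.measurements:
            assert m.total_angle == 180.0 - m.left_angle - m.right_angle

    def test_avulsion_gap_disables_only_plane_one(self):
        spec = PhantomSpec(avulsion=("left", 0.25 * 80.0))
        mask, ls, _ = generate_phantom(spec)
        prof = measure_subject(mask, ls)
        flags = {m.plane_index: m.measurable for m in prof.measurements}
        assert flags == {1: False, 2: True, 3: True, 4: True, 5: True}

    def test_rigid_motion_invariance(self, varied_phantom):
        mask, ls, _ = varied_phantom
        base = measure_subject(mask, ls)
        rng = np.random.default_rng(42)
        R = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        mask2, ls2 = transform_scene(mask, ls, R, t)
        moved = measure_subject(mask2, ls2)
        for a, b in zip(base.measurements, moved.measurements):
            assert b.left_angle == pytest.approx(a.left_angle, abs=0.5)
            assert b.right_angle == pytest.approx(a.right_angle, abs=0.5)

    def test_mirror_symmetry_swaps_sides(self, varied_phantom):
        mask, ls, _ = varied_phantom
        base = measure_subject(mask, ls)
        mirrored_mask = VolumeMask(voxels=mask.voxels, affine=np.diag([-1.0, 1, 1, 1]) @ mask.affine)
        mirrored = measure_subject(mirrored_mask, ls.mirrored())
        for a, b in zip(base.measurements, mirrored.measurements):
            assert b.left_angle == pytest.approx(a.right_angle, abs=1e-9)
            assert b.right_angle == pytest.approx(a.left_angle, abs=1e-9)

    def test_steeper_sheets_give_strictly_smaller_totals(self):
        totals = []
        for angle in (20.0, 35.0, 50.0, 65.0):
            spec = PhantomSpec(left_angles=(angle,) * 5, right_angles=(angle,) * 5)
            mask, ls, _ = generate_phantom(spec)
            prof = measure_subject(mask, ls)
            totals.append(np.mean([m.total_angle for m in prof.measurements]))
        assert all(a > b for a, b in zip(totals, totals[1:]))

    def test_empty_mask_raises_with_subject_context(self, symmetric_phantom):
        mask, ls, _ = symmetric_phantom
        empty = VolumeMask(voxels=np.zeros_like(mask.voxels), affine=mask.affine)
        with pytest.raises(GeometryError, match="subj-9"):
            measure_subject(empty, ls, subject_id="subj-9")
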