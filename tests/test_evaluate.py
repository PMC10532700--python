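"""Landmark geometry, projected angles, registration/overlap/screw metrics."""

import numpy as np
import pytest

from postop3d.errors import DetectionFailure, MisuseError
from postop3d.evaluate import (AnatomicalAxes, EvaluationReport, compare_solutions,
                               dice_coefficient, landmark_points, match_screws,
                               normal_angle, projected_angles,
                               registration_errors, screw_errors, surface_points)
from postop3d.geometry import Plane, RigidTransform, angle_between_deg, unit
from postop3d.registration import orient_planes
from postop3d.screws import ScrewDetection
from postop3d.volume import LabelVolume


def _sphere_surface(r=20.0, n=4000, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    return r * v / np.linalg.norm(v, axis=1, keepdims=True)


# -- landmarks ----------------------------------------------------------------


def test_most_superior_point_on_sphere_plane_intersection():
    # plane y = 0 cuts the sphere in a circle in the x-z plane; with
    # superior = +z the most superior intersection point is (0, 0, r)
    surface = _sphere_surface()
    planes = [Plane(np.zeros(3), np.array([0.0, 1.0, 0.0])),
              Plane(np.array([0.0, -5.0, 0.0]), np.array([0.0, 1.0, 0.0])),
              Plane(np.array([0.0, 0.0, -5.0]), np.array([0.0, 0.0, 1.0])),
              Plane(np.array([5.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))]
    lm = landmark_points(planes, surface, tol=1.0)
    p1 = lm.points["P1"]
    assert p1 is not None
    assert np.linalg.norm(p1 - [0.0, 0.0, 20.0]) < 2.5  # finite sampling of the circle


def test_parallel_planes_flag_landmark_failure():
    surface = _sphere_surface()
    n = np.array([0.0, 1.0, 0.0])
    planes = [Plane(np.zeros(3), n), Plane(np.array([0.0, 3.0, 0.0]), n),
              Plane(np.array([0.0, 0.0, -5.0]), np.array([0.0, 0.0, 1.0])),
              Plane(np.array([5.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))]
    lm = landmark_points(planes, surface, tol=1.0)
    assert "P2" in lm.failed and lm.points["P2"] is None


def test_phantom_landmarks_near_analytic_extrema(phantom_noise_free):
    """Each landmark lands within 2 voxel diagonals of the extremum computed
    on a dense analytic evaluation of the same surface/plane geometry."""
    pre, post, truth = phantom_noise_free
    oriented = orient_planes(truth.planes)
    surface = surface_points(truth.post_bone_label)
    lm = landmark_points(oriented, surface)
    diag2 = 2 * np.sqrt(3.0)
    axes = AnatomicalAxes()
    # dense oracle for P1/P4/P5: exhaustive extremum over the tolerance band
    for name, plane, direction in (("P1", oriented[0], axes.superior),
                                   ("P4", oriented[2], axes.anterior),
                                   ("P5", oriented[3], axes.posterior)):
        band = surface[np.abs(plane.signed_distance(surface)) <= np.sqrt(3) / 2]
        oracle = band[np.argmax(band @ direction)]
        assert np.linalg.norm(lm.points[name] - oracle) <= diag2


def test_empty_surface_rejected():
    planes = [Plane(np.zeros(3), np.array([0.0, 0.0, 1.0]))] * 4
    with pytest.raises(MisuseError):
        landmark_points(planes, np.empty((0, 3)))


# -- projected angles ---------------------------------------------------------


def test_square_corners_give_right_angles():
    p1, p2, p3, p4 = [np.array(p, float) for p in
                      ((0, 0, 0), (10, 0, 0), (10, 10, 0), (0, 10, 0))]
    ang = projected_angles(p1, p2, p3, p4)
    assert ang.sr == pytest.approx(90.0, abs=1e-9)
    assert ang.ri == pytest.approx(90.0, abs=1e-9)


def test_projection_identity_for_coplanar_points():
    pts = [np.array(p, float) for p in ((0, 0, 2), (8, 1, 2), (9, 7, 2), (1, 6, 2))]
    ang = projected_angles(*pts)
    proj = ang.plane.project(np.array(pts))
    np.testing.assert_allclose(proj, pts, atol=1e-9)


def test_angle_matches_direct_formula_on_random_points():
    rng = np.random.default_rng(1)
    pts = rng.uniform(-20, 20, size=(4, 3))
    ang = projected_angles(*pts)
    v1, v2 = ang.vectors[0], ang.vectors[1]
    direct = np.degrees(np.arccos(
        np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))
    assert ang.sr == pytest.approx(direct, abs=1e-9)


def test_angles_invariant_under_common_rigid_transform():
    rng = np.random.default_rng(2)
    pts = rng.uniform(-20, 20, size=(4, 3))
    t = RigidTransform.from_axis_angle(rng.normal(size=3), 37.0,
                                       translation=[5, -8, 11])
    a = projected_angles(*pts)
    b = projected_angles(*t.apply(pts))
    assert a.sr == pytest.approx(b.sr, abs=1e-9)
    assert a.ri == pytest.approx(b.ri, abs=1e-9)


# -- normal angle -------------------------------------------------------------


@pytest.mark.parametrize("n_a,n_b,expected", [
    ((0, 0, 1), (0, 0, 1), 0.0),
    ((0, 0, 1), (0, 0, -1), 0.0),       # sign-agnostic
    ((1, 0, 0), (1, 1, 0), 45.0),
])
def test_normal_angle_values(n_a, n_b, expected):
    assert normal_angle(unit(np.array(n_a, float)), unit(np.array(n_b, float))) \
        == pytest.approx(expected, abs=1e-9)


# -- registration errors ------------------------------------------------------


def test_registration_errors_identity_and_pythagoras():
    pts = _sphere_surface(n=100)
    t = RigidTransform.from_axis_angle([0, 1, 0], 12.0)
    assert registration_errors(pts, t, t) == 0.0
    ta = RigidTransform.from_translation([3.0, 0.0, 0.0])
    tb = RigidTransform.from_translation([0.0, -4.0, 0.0])
    assert registration_errors(pts, ta, tb) == pytest.approx(5.0, abs=1e-12)


def test_registration_errors_matches_brute_force():
    rng = np.random.default_rng(3)
    pts = _sphere_surface(n=1000, seed=3)
    ta = RigidTransform.from_axis_angle(rng.normal(size=3), 9.0, translation=[1, 2, 3])
    tb = RigidTransform.from_axis_angle(rng.normal(size=3), 4.0, translation=[-2, 0, 1])
    brute = np.mean([np.linalg.norm(ta.apply(p) - tb.apply(p)) for p in pts])
    assert registration_errors(pts, ta, tb) == pytest.approx(brute, abs=1e-9)
    with pytest.raises(MisuseError):
        registration_errors(np.empty((0, 3)), ta, tb)


# -- dice ---------------------------------------------------------------------


def test_dice_identical_disjoint_and_counted():
    a = np.zeros((10, 10, 10), dtype=np.int16)
    a[:5] = 1
    va = LabelVolume(a)
    assert dice_coefficient(va, va) == 1.0
    b = np.zeros_like(a)
    b[5:] = 1
    assert dice_coefficient(va, LabelVolume(b)) == 0.0
    c = np.zeros_like(a)
    c[2:7] = 1  # |A|=500, |C|=500, overlap 300
    assert dice_coefficient(va, LabelVolume(c)) == pytest.approx(
        2 * 300 / (500 + 500), abs=1e-12)
    with pytest.raises(MisuseError):
        dice_coefficient(LabelVolume(np.zeros_like(a)), LabelVolume(np.zeros_like(a)))


def test_dice_symmetric(phantom_one):
    _, _, truth = phantom_one
    a, b = truth.fragment_label, truth.post_bone_label
    assert dice_coefficient(a, b) == dice_coefficient(b, a)


# -- screw comparison ---------------------------------------------------------


def _detection(entry, direction, n=500):
    return ScrewDetection(n_points=n, center=np.asarray(entry, float) - 20.0,
                          direction=unit(np.asarray(direction, float)),
                          entry_point=np.asarray(entry, float))


def test_screw_errors_zero_for_identical_sets():
    dets = [_detection([10, 10, 50], [0, 0, 1]), _detection([30, 10, 52], [0.1, 0, 1])]
    out = screw_errors(dets, dets)
    assert out["mean_head_mm"] == 0.0
    assert out["mean_axis_deg"] == pytest.approx(0.0, abs=1e-9)
    assert out["unmatched_auto"] == [] and out["unmatched_ref"] == []


def test_screw_errors_report_known_2deg_perturbation():
    ref = [_detection([10, 10, 50], [0, 0, 1])]
    rot = RigidTransform.from_axis_angle([1, 0, 0], 2.0)
    auto = [_detection([10, 10, 50], rot.apply_vector(np.array([0.0, 0.0, 1.0])))]
    out = screw_errors(auto, ref)
    assert out["matched"][0]["axis_deg"] == pytest.approx(2.0, abs=1e-6)


def test_match_gate_leaves_far_detections_unmatched():
    ref = [_detection([10, 10, 50], [0, 0, 1])]
    auto = [_detection([40, 10, 50], [0, 0, 1])]  # 30 mm away, beyond 10 mm gate
    out = screw_errors(auto, ref)
    assert out["matched"] == []
    assert out["unmatched_auto"] == [0] and out["unmatched_ref"] == [0]


def test_match_is_mutual_nearest():
    ref_entries = np.array([[0, 0, 0], [6.0, 0, 0]])
    auto_entries = np.array([[1.0, 0, 0], [5.0, 0, 0]])
    pairs = match_screws(auto_entries, ref_entries)
    assert sorted(pairs) == [(0, 0), (1, 1)]


# -- report -------------------------------------------------------------------


def test_report_round_trips_through_json():
    rep = EvaluationReport(plane_normal_angles_deg=[0.5, 1.0, 0.2, 2.0],
                           err_t1_mm=1.01, dice_auto=0.62,
                           landmark_distances_mm={"P1": 17.0})
    back = EvaluationReport.from_json(rep.to_json())
    assert back.to_dict() == rep.to_dict()


def test_compare_solutions_self_comparison_is_zero(phantom_noise_free):
    _, _, truth = phantom_noise_free
    oriented = orient_planes(truth.planes)
    surface = surface_points(truth.post_bone_label)
    rep = compare_solutions(oriented, oriented, surface)
    assert max(rep.plane_normal_angles_deg) < 1e-9
    assert max(rep.plane_center_offsets_mm) < 1e-9
    assert rep.sr_deviation_deg == pytest.approx(0.0, abs=1e-9)
    assert all(v == pytest.approx(0.0, abs=1e-9)
               for v in rep.landmark_distances_mm.values())
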