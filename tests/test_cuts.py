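"""Losses, PCA plane fitting and cut-region detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from postop3d.cuts import (ClassProbabilities, OracleSegmenter, SegmenterSpec,
                           dice_ce_loss, detect_planes, fit_plane,
                           segment_cut_regions, train_segmenter, wcce_loss)
from postop3d.errors import DegenerateInputError, MisuseError
from postop3d.geometry import RigidTransform
from postop3d.volume import LabelVolume, Volume
from conftest import sign_agnostic_angle_deg

EPS = 1e-7


# -- weighted categorical cross-entropy -------------------------------------


def test_wcce_hand_computed_single_voxel():
    probs = ClassProbabilities(target=[[1.0, 0.0]], predicted=[[0.5, 0.5]],
                               weights=[1.0, 1.0])
    assert wcce_loss(probs) == pytest.approx(-np.log(0.5), abs=1e-9)


def test_wcce_perfect_prediction_is_clipping_limited():
    t = np.eye(3)[np.random.default_rng(0).integers(0, 3, size=(4, 4))]
    probs = ClassProbabilities(t, t, weights=[10.0, 270.0, 260.0])
    assert wcce_loss(probs) <= 270.0 * abs(np.log(1 - EPS)) + 1e-12


def test_wcce_with_unit_weights_equals_plain_cross_entropy():
    rng = np.random.default_rng(1)
    p = rng.dirichlet(np.ones(5), size=(6, 6))
    t = np.eye(5)[rng.integers(0, 5, size=(6, 6))]
    ours = wcce_loss(ClassProbabilities(t, p, weights=np.ones(5)))
    plain = float(-(t * np.log(np.clip(p, EPS, 1 - EPS))).sum(axis=-1).mean())
    assert abs(ours - plain) < 1e-9


def test_wcce_shape_mismatch_rejected():
    with pytest.raises(MisuseError):
        ClassProbabilities(np.zeros((2, 3)), np.zeros((2, 4)), weights=np.ones(4))


# -- Dice-CE ----------------------------------------------------------------


def test_dice_ce_perfect_prediction_near_zero():
    t = np.array([1.0, 0.0, 1.0, 1.0])
    assert dice_ce_loss(t, t) <= 1e-3


def test_dice_ce_endpoints_are_pure_terms():
    rng = np.random.default_rng(2)
    p = rng.uniform(0.01, 0.99, size=8)
    t = (rng.uniform(size=8) > 0.5).astype(float)
    ce = float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())
    dice = (2 * (p * t).sum() + EPS) / (p.sum() + t.sum() + EPS)
    assert dice_ce_loss(p, t, alpha=0.0) == pytest.approx(ce, abs=1e-9)
    assert dice_ce_loss(p, t, alpha=1.0) == pytest.approx(1 - dice, abs=1e-9)


def test_dice_ce_two_voxel_hand_evaluation():
    # pred = 0.5 everywhere, target = (1, 0): CE = -log(0.5),
    # soft dice = 2*0.5/(1+1) = 0.5 -> loss(0.5) = 0.5*log(2) + 0.25
    p = np.array([0.5, 0.5])
    t = np.array([1.0, 0.0])
    expected = 0.5 * np.log(2.0) + 0.5 * (1 - (2 * 0.5 + EPS) / (2.0 + EPS))
    assert dice_ce_loss(p, t, alpha=0.5) == pytest.approx(expected, abs=1e-9)


def test_dice_ce_alpha_out_of_range():
    with pytest.raises(MisuseError):
        dice_ce_loss(np.zeros(3), np.zeros(3), alpha=1.5)


# -- plane fitting -----------------------------------------------------------


def test_fit_plane_exact_coplanar_points():
    rng = np.random.default_rng(3)
    pts = np.column_stack([rng.uniform(-10, 10, 50), rng.uniform(-10, 10, 50),
                           np.full(50, 5.0)])
    plane = fit_plane(pts)
    assert sign_agnostic_angle_deg(plane.normal, [0, 0, 1]) < 1e-9
    assert plane.center[2] == pytest.approx(5.0, abs=1e-12)
    assert np.abs(plane.signed_distance(pts)).max() < 1e-9


def test_fit_plane_noisy_matches_svd_oracle_within_1deg():
    rng = np.random.default_rng(4)
    normal = np.array([1.0, 2.0, 2.0]) / 3.0
    u = np.linalg.qr(np.column_stack([normal, rng.normal(size=(3, 2))]))[0][:, 1:]
    pts = (rng.uniform(-20, 20, size=(500, 2)) @ u.T
           + rng.normal(0, 0.1, size=(500, 3)))
    plane = fit_plane(pts)
    assert sign_agnostic_angle_deg(plane.normal, normal) < 1.0
    # independent oracle: SVD of the mean-centered cloud
    _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
    assert sign_agnostic_angle_deg(plane.normal, vt[-1]) < 1e-6


def test_fit_plane_invariant_under_duplication():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(40, 3)) * [5, 4, 0.2]
    a = fit_plane(pts)
    b = fit_plane(np.vstack([pts, pts]))
    np.testing.assert_allclose(a.center, b.center, atol=1e-9)
    assert sign_agnostic_angle_deg(a.normal, b.normal) < 1e-9


def test_fit_plane_degenerate_inputs():
    with pytest.raises(DegenerateInputError):
        fit_plane(np.zeros((2, 3)))
    line = np.outer(np.linspace(0, 1, 30), [1.0, 2.0, 3.0])
    with pytest.raises(DegenerateInputError):
        fit_plane(line)


@settings(deadline=None, max_examples=15, derandomize=True)
@given(st.integers(0, 2 ** 16))
def test_fit_plane_residual_rms_rigid_invariant(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(60, 3)) * [6, 5, 0.3]
    t = RigidTransform.from_axis_angle(rng.normal(size=3), rng.uniform(0, 180),
                                       translation=rng.uniform(-30, 30, 3))
    def rms(p):
        plane = fit_plane(p)
        return np.sqrt(np.mean(plane.signed_distance(p) ** 2))
    assert abs(rms(pts) - rms(t.apply(pts))) < 1e-6


# -- cut-region detection ----------------------------------------------------


def test_oracle_backend_returns_truth_labels(phantom_noise_free):
    pre, post, truth = phantom_noise_free
    labels = segment_cut_regions(post, OracleSegmenter(truth.cut_labels))
    assert np.array_equal(labels.values, truth.cut_labels.values)
    assert set(np.unique(labels.values)) <= {0, 1, 2, 3, 4}


def test_detect_planes_recovers_phantom_planes(phantom_noise_free):
    pre, post, truth = phantom_noise_free
    det = detect_planes(post, OracleSegmenter(truth.cut_labels))
    assert det.all_ok
    for plane, true_plane in zip(det.planes, truth.planes):
        assert sign_agnostic_angle_deg(plane.normal, true_plane.normal) < 2.0
        assert abs(true_plane.signed_distance(plane.center)) < 2.0


def test_detect_planes_flags_erased_region(phantom_noise_free):
    pre, post, truth = phantom_noise_free
    labels = truth.cut_labels.values.copy()
    labels[labels == 2] = 0
    erased = LabelVolume(labels, truth.cut_labels.spacing, truth.cut_labels.origin,
                         truth.cut_labels.axes)
    det = detect_planes(post, OracleSegmenter(erased))
    assert det.failed == [False, True, False, False]
    assert det.planes[1] is None
    assert sum(p is not None for p in det.planes) == 3


def test_detect_planes_spacing_invariant(phantom_noise_free):
    """World-mm fitting: an anisotropic-spacing relabelling of the same
    geometry yields the same planes as the isotropic original."""
    from postop3d import resample
    pre, post, truth = phantom_noise_free
    aniso = resample(truth.cut_labels, (96, 48, 96), "nearest")
    det_iso = detect_planes(post, OracleSegmenter(truth.cut_labels))
    post_aniso = Volume(np.zeros(aniso.shape), aniso.spacing, aniso.origin, aniso.axes)
    det_aniso = detect_planes(post_aniso, OracleSegmenter(aniso))
    for a, b in zip(det_iso.planes, det_aniso.planes):
        assert sign_agnostic_angle_deg(a.normal, b.normal) < 3.0


def test_network_backend_misuse_message():
    with pytest.raises(MisuseError):
        segment_cut_regions(Volume(np.zeros((8, 8, 8))), backend="network")


# -- training (desk scale) ---------------------------------------------------


def _toy_cases(n, grid=32, seed=0):
    """Trivially separable cases: cut labels sit on bright slabs."""
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        labels = np.zeros((grid,) * 3, dtype=np.int16)
        img = rng.normal(0.2, 0.02, size=(grid,) * 3).astype(np.float32)
        for j in range(1, 5):
            lo = 4 + 6 * (j - 1)
            labels[lo:lo + 3, 4:grid - 4, 4 * j:4 * j + 8] = j
        img[labels > 0] += 0.6
        img += rng.normal(0, 0.02, img.shape).astype(np.float32)
        cases.append((Volume(img), LabelVolume(labels)))
    return cases


def test_training_decreases_wcce_and_is_seed_deterministic():
    spec = SegmenterSpec.cut_default(grid=32, epochs=3)
    cases = _toy_cases(3)
    seg_a = train_segmenter(spec, cases, seed=5)
    seg_b = train_segmenter(spec, cases, seed=5)
    assert seg_a.loss_trace[-1] < seg_a.loss_trace[0]
    assert seg_a.loss_trace == seg_b.loss_trace


def test_training_overfits_single_separable_case():
    spec = SegmenterSpec.cut_default(grid=32, epochs=8)
    cases = _toy_cases(2, seed=1)
    seg = train_segmenter(spec, cases, seed=3)
    img, lab = cases[0]
    pred = seg.predict(img)
    for j in range(1, 5):
        truth_j = lab.values == j
        recall = (pred.values[truth_j] == j).mean()
        assert recall > 0.5


def test_training_validates_inputs():
    spec = SegmenterSpec.cut_default(grid=32, epochs=1)
    with pytest.raises(MisuseError):
        train_segmenter(spec, _toy_cases(1), seed=0)
    bad = _toy_cases(2)
    bad[0] = (Volume(np.zeros((8, 8, 8))), bad[0][1])
    with pytest.raises(MisuseError):
        train_segmenter(spec, bad, seed=0)


def test_spec_validation():
    with pytest.raises(MisuseError):
        SegmenterSpec(lr_schedule=((0, 20, 1e-4),), epochs=40)  # gap
    with pytest.raises(MisuseError):
        SegmenterSpec(lr_schedule=((0, 40, -1.0),))
    with pytest.raises(MisuseError):
        SegmenterSpec(n_classes=5, class_weights=(1.0, 2.0))
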