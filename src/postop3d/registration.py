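"""Fragment repositioning by masked two-stage rigid registration.

Stage one (coarse) rigidly aligns the whole preoperative CT to the
postoperative CT, restricting the normalized-correlation metric to the
pelvis-bone mask.  Stage two (fine) registers only the acetabular
fragment: the four detected cut planes are oriented toward the joint
center (approximated as the mean of the plane centers), a voxel of the
pelvis mask belongs to the fragment iff its signed dot product with every
oriented plane is strictly positive, and registration restricted to that
fragment mask yields the residual fragment transform.

Transforms follow the convention that they map pre-image world
coordinates into post-image world coordinates; resampling uses the
inverse.  The optimizer is ITK's regular-step gradient descent on a
versor-parameterized rigid transform (via SimpleITK), with the parameter
scaling, step bounds and iteration caps exposed in
:class:`RegistrationParams`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import DegenerateInputError, EmptyFragmentError, MisuseError
from .geometry import Plane, RigidTransform
from .volume import LabelVolume, Volume


@dataclass
class RegistrationParams:
    """Regular-step gradient-descent hyperparameters.

    ``translation_scale``/``rotation_scale`` weight the parameter axes
    (a smaller scale lets that parameter move further per step);
    ``max_step``/``min_step`` bound the step length (mm in scaled space)
    and ``sampling`` is the fraction of in-mask voxels used by the metric
    (1.0 = all voxels, deterministic).
    """

    iterations: int = 200
    translation_scale: float = 1.0 / 2000.0
    rotation_scale: float = 1.0
    max_step: float = 1.0
    min_step: float = 0.001
    sampling: float = 1.0

    def __post_init__(self) -> None:
        if self.iterations <= 0:
            raise MisuseError("iterations must be positive")
        if not (self.max_step > self.min_step > 0):
            raise MisuseError("require max_step > min_step > 0")
        if not (0 < self.sampling <= 1):
            raise MisuseError("sampling must lie in (0, 1]")

    @classmethod
    def coarse_default(cls) -> "RegistrationParams":
        """Whole-pelvis alignment defaults."""
        return cls()

    @classmethod
    def fine_default(cls) -> "RegistrationParams":
        """Fragment alignment defaults."""
        return cls(translation_scale=1.0 / 500.0, max_step=0.7, min_step=0.0001)


@dataclass
class RegistrationResult:
    transform: RigidTransform
    converged: bool
    metric_value: float          # normalized correlation at the optimum
    iterations_used: int
    stop_description: str


@dataclass
class RepositioningReport:
    coarse: RegistrationResult
    fine: RegistrationResult
    fragment_voxels: int
    joint_center: np.ndarray

    def to_dict(self) -> dict:
        return {
            "coarse": {
                "converged": self.coarse.converged,
                "metric": self.coarse.metric_value,
                "iterations": self.coarse.iterations_used,
            },
            "fine": {
                "converged": self.fine.converged,
                "metric": self.fine.metric_value,
                "iterations": self.fine.iterations_used,
            },
            "fragment_voxels": self.fragment_voxels,
            "joint_center": np.asarray(self.joint_center).tolist(),
        }


# -- similarity metric ------------------------------------------------------


def normalized_correlation(fixed: Volume, moving: Volume, mask: LabelVolume) -> float:
    """Pearson correlation of intensities over the in-mask voxels."""
    if not fixed.same_grid_as(moving) or not fixed.same_grid_as(mask):
        raise MisuseError("normalized_correlation requires a common grid")
    sel = mask.values > 0
    if not sel.any():
        raise MisuseError("mask is empty")
    a = fixed.values[sel].astype(float)
    b = moving.values[sel].astype(float)
    a -= a.mean()
    b -= b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateInputError("constant intensities within the mask")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


# -- SimpleITK bridge -------------------------------------------------------


def _itk_from_rigid(t: RigidTransform, center: np.ndarray) -> sitk.VersorRigid3DTransform:
    tx = sitk.VersorRigid3DTransform()
    tx.SetCenter(tuple(float(c) for c in center))
    tx.SetMatrix(tuple(float(v) for v in t.rotation.flatten()), 1e-8)
    # VersorRigid3D maps x -> R (x - c) + c + t ; solve for its t
    offs = t.translation + t.rotation @ center - center
    tx.SetTranslation(tuple(float(v) for v in offs))
    return tx


def _rigid_from_itk(tx: sitk.Transform) -> RigidTransform:
    tx = sitk.VersorRigid3DTransform(tx)
    R = np.array(tx.GetMatrix()).reshape(3, 3)
    c = np.array(tx.GetCenter())
    t = np.array(tx.GetTranslation())
    return RigidTransform.from_rotation_translation(R, t + c - R @ c)


def resample_to(moving: Volume, reference: Volume,
                transform: RigidTransform | None = None) -> Volume:
    """Resample ``moving`` onto ``reference``'s grid.

    ``transform`` maps moving-image world coordinates into reference
    world coordinates (identity if None); label volumes use
    nearest-neighbour interpolation.
    """
    transform = transform or RigidTransform.identity()
    is_labels = isinstance(moving, LabelVolume)
    mimg = moving.to_sitk()
    rimg = reference.to_sitk()
    itk_t = sitk.AffineTransform(3)
    inv = transform.inverse()  # ITK resampling wants reference -> moving
    itk_t.SetMatrix(tuple(float(v) for v in inv.rotation.flatten()))
    itk_t.SetTranslation(tuple(float(v) for v in inv.translation))
    interp = sitk.sitkNearestNeighbor if is_labels else sitk.sitkLinear
    out = sitk.Resample(mimg, rimg, itk_t, interp, float(np.min(moving.values)))
    vol = Volume.from_sitk(out)
    if is_labels:
        return LabelVolume(np.round(vol.values).astype(np.int16), vol.spacing,
                           vol.origin, vol.axes, label_set=moving.label_set)
    return vol


# -- rigid registration -----------------------------------------------------


def register_rigid(fixed: Volume, moving: Volume, mask: LabelVolume,
                   params: RegistrationParams | None = None,
                   init: RigidTransform | None = None) -> RegistrationResult:
    """Masked 6-DOF rigid registration of ``moving`` onto ``fixed``.

    ``mask`` restricts the metric and must live on the fixed grid.  The
    returned transform maps moving world coordinates into fixed world
    coordinates.  With full sampling the optimization is deterministic.
    """
    params = params or RegistrationParams.coarse_default()
    if not fixed.same_grid_as(mask):
        raise MisuseError("mask must be defined on the fixed grid")
    sel = mask.values > 0
    if not sel.any():
        raise MisuseError("mask is empty")
    if np.ptp(fixed.values[sel]) == 0:
        raise DegenerateInputError("constant fixed intensities within the mask")
    init = init or RigidTransform.identity()
    center = mask.voxel_centers_world(sel).mean(axis=0)

    fimg = sitk.Cast(fixed.to_sitk(), sitk.sitkFloat32)
    mimg = sitk.Cast(moving.to_sitk(), sitk.sitkFloat32)
    mask_img = sitk.Cast(mask.with_values((sel).astype(np.uint8)).to_sitk(), sitk.sitkUInt8)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetMetricFixedMask(mask_img)
    reg.SetInterpolator(sitk.sitkLinear)
    if params.sampling >= 1.0:
        reg.SetMetricSamplingStrategy(reg.NONE)
    else:
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(params.sampling)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=params.max_step,
        minStep=params.min_step,
        numberOfIterations=params.iterations,
        relaxationFactor=0.5,
        gradientMagnitudeTolerance=1e-12,  # stop on step size, not slope
    )
    reg.SetOptimizerScales([params.rotation_scale] * 3 + [params.translation_scale] * 3)

    # ITK transforms map fixed physical points to moving physical points,
    # the inverse of this package's pre->post convention.
    tx = _itk_from_rigid(init.inverse(), center)
    reg.SetInitialTransform(tx, inPlace=True)
    out = reg.Execute(fimg, mimg)

    stop = reg.GetOptimizerStopConditionDescription()
    converged = "Step too small" in stop or "StepTooSmall" in stop
    transform = _rigid_from_itk(out).inverse()
    # report the plain Pearson correlation at the optimum (ITK's internal
    # metric is its negative square)
    metric = normalized_correlation(fixed, resample_to(moving, fixed, transform), mask)
    return RegistrationResult(
        transform=transform,
        converged=converged,
        metric_value=metric,
        iterations_used=int(reg.GetOptimizerIteration()),
        stop_description=stop,
    )


# -- fragment isolation -----------------------------------------------------


def orient_planes(planes: list[Plane]) -> list[Plane]:
    """Flip each plane normal to point toward the joint center (the mean
    of the four plane centers); centers are unchanged."""
    if len(planes) != 4:
        raise MisuseError("orient_planes expects exactly 4 planes")
    center = np.mean([p.center for p in planes], axis=0)
    out = []
    for p in planes:
        d = float((center - p.center) @ p.normal)
        if d == 0.0:
            warnings.warn("joint center lies exactly on a cut plane; "
                          "normal left as-is", stacklevel=2)
            out.append(Plane(p.center.copy(), p.normal.copy()))
        else:
            out.append(p if d > 0 else p.flipped())
    return out


def joint_center(planes: list[Plane]) -> np.ndarray:
    return np.mean([p.center for p in planes], axis=0)


def build_fragment_mask(coarse_mask: LabelVolume, planes: list[Plane]) -> LabelVolume:
    """Fragment = mask voxels strictly on the joint-center side of all
    four oriented planes (dot product > 0 for every plane)."""
    if len(planes) != 4:
        raise MisuseError("build_fragment_mask expects exactly 4 planes")
    sel = coarse_mask.values > 0
    idx = np.argwhere(sel)
    pts = coarse_mask.world_from_voxel(idx)
    keep = np.ones(len(pts), dtype=bool)
    for p in planes:
        keep &= p.signed_distance(pts) > 0.0
    if not keep.any():
        raise EmptyFragmentError("no mask voxel lies strictly inside all four planes")
    values = np.zeros(coarse_mask.shape, dtype=np.int16)
    kept = idx[keep]
    values[kept[:, 0], kept[:, 1], kept[:, 2]] = 1
    return LabelVolume(values, coarse_mask.spacing.copy(), coarse_mask.origin.copy(),
                       coarse_mask.axes.copy())


# -- full repositioning quantification --------------------------------------


def quantify_repositioning(
    pre: Volume,
    post: Volume,
    planes: list[Plane],
    pelvis_mask: LabelVolume,
    coarse_params: RegistrationParams | None = None,
    fine_params: RegistrationParams | None = None,
    pre_pelvis_mask: LabelVolume | None = None,
) -> tuple[RigidTransform, RigidTransform, RepositioningReport]:
    """Two-stage quantification of the fragment repositioning.

    ``pelvis_mask`` is the postoperative pelvis-bone mask (network or
    oracle backend) on the post grid; ``planes`` are the four detected cut
    planes in the post frame.  Returns ``(T1, T2, report)`` where ``T1``
    maps pre world coordinates into post world coordinates (whole-body
    coarse alignment) and ``T2`` is the residual fragment transform; the
    composition ``T2 ∘ T1`` maps the preoperative fragment onto its
    postoperative position.  ``pre_pelvis_mask`` (pre grid), when given,
    initializes the coarse stage by aligning mask centroids.
    """
    coarse_params = coarse_params or RegistrationParams.coarse_default()
    fine_params = fine_params or RegistrationParams.fine_default()

    if pre_pelvis_mask is not None:
        c_pre = pre_pelvis_mask.voxel_centers_world(pre_pelvis_mask.values > 0).mean(axis=0)
        c_post = pelvis_mask.voxel_centers_world(pelvis_mask.values > 0).mean(axis=0)
        init = RigidTransform.from_translation(c_post - c_pre)
    else:
        init = RigidTransform.identity()

    coarse_res = register_rigid(post, pre, pelvis_mask, coarse_params, init=init)
    t1 = coarse_res.transform

    oriented = orient_planes(planes)
    frag_mask = build_fragment_mask(pelvis_mask, oriented)

    pre_aligned = resample_to(pre, post, t1)
    fine_res = register_rigid(post, pre_aligned, frag_mask, fine_params)
    t2 = fine_res.transform

    report = RepositioningReport(
        coarse=coarse_res,
        fine=fine_res,
        fragment_voxels=int((frag_mask.values > 0).sum()),
        joint_center=joint_center(oriented),
    )
    return t1, t2, report
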