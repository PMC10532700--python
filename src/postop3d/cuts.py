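"""Osteotomy detection and quantification.

Per-voxel cut-region labels (1..4, one per osteotomy) come from a
pluggable segmentation backend — either the 3D U-Net trained with a
weighted categorical cross-entropy, or an oracle that replays phantom
ground truth so the geometric pipeline can be exercised without trained
weights.  A plane is then fitted to each labelled region by PCA: the
center of mass is the plane center and the eigenvector of the point
covariance with the smallest eigenvalue is the plane normal (sign
resolved later by orienting toward the joint center).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, MisuseError
from .geometry import Plane
from .nn import Adam, UNet3D
from .volume import LabelVolume, Volume

_EPS = 1e-7

#: empirically determined voxel-class weights for the cut-region loss
#: (background, cut 1..4)
DEFAULT_CUT_WEIGHTS = (10.0, 270.0, 260.0, 270.0, 260.0)


# -- losses -----------------------------------------------------------------


@dataclass
class ClassProbabilities:
    """Per-voxel one-hot targets, predicted probabilities and class weights.

    ``target`` and ``predicted`` have shape (..., n_classes); ``weights``
    has length n_classes.
    """

    target: np.ndarray
    predicted: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if self.target.shape != self.predicted.shape:
            raise MisuseError(
                f"target shape {self.target.shape} != predicted shape {self.predicted.shape}")
        if self.target.shape[-1] != len(self.weights):
            raise MisuseError("weights length must equal the number of classes")
        if np.any(self.predicted < 0) or np.any(self.predicted > 1):
            raise MisuseError("predicted probabilities must lie in [0, 1]")
        sums = self.predicted.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > 1e-5):
            raise MisuseError("predicted probabilities must sum to 1 per voxel")


def wcce_loss(probs: ClassProbabilities) -> float:
    """Weighted categorical cross-entropy, averaged over voxels.

    Per voxel: ``-sum_i t_i * log(p_i) * w_i`` with the sum running over
    classes; predictions are clipped to [eps, 1 - eps], eps = 1e-7.
    """
    p = np.clip(probs.predicted, _EPS, 1.0 - _EPS)
    per_voxel = -(probs.target * np.log(p) * probs.weights).sum(axis=-1)
    return float(per_voxel.mean())


def dice_ce_loss(pred: np.ndarray, target: np.ndarray, alpha: float = 0.5) -> float:
    """Convex combination of binary cross-entropy and soft-Dice loss:
    ``(1 - alpha) * L_CE + alpha * (1 - soft_dice)``, default alpha 0.5."""
    if not 0.0 <= alpha <= 1.0:
        raise MisuseError("alpha must lie in [0, 1]")
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise MisuseError("pred and target must have the same shape")
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    ce = float(-(target * np.log(p) + (1 - target) * np.log(1 - p)).mean())
    inter = float((pred * target).sum())
    denom = float(pred.sum() + target.sum())
    dice = (2 * inter + _EPS) / (denom + _EPS)
    return (1 - alpha) * ce + alpha * (1 - dice)


def _wcce_grad_logits(target: np.ndarray, probs: np.ndarray,
                      weights: np.ndarray) -> np.ndarray:
    """Gradient of mean WCCE w.r.t. softmax logits."""
    n_vox = np.prod(target.shape[:-1])
    wt = (target * weights).sum(axis=-1, keepdims=True)
    return (probs * wt - target * weights) / n_vox


def _dice_ce_grad_logits(target: np.ndarray, probs: np.ndarray,
                         alpha: float) -> np.ndarray:
    """Gradient of Dice-CE w.r.t. sigmoid logits."""
    n_vox = probs.size
    g_ce = (probs - target) / n_vox
    inter = (probs * target).sum()
    denom = probs.sum() + target.sum()
    g_dice_p = -(2 * target * (denom + _EPS) - (2 * inter + _EPS)) / (denom + _EPS) ** 2
    g_dice = g_dice_p * probs * (1 - probs)
    return (1 - alpha) * g_ce + alpha * g_dice


# -- segmenter spec + training ---------------------------------------------


@dataclass
class SegmenterSpec:
    """Architecture and schedule of the volumetric segmenter.

    ``lr_schedule`` is a list of ``(epoch_start, epoch_end, rate)`` triples
    that must tile ``[0, epochs)``.  ``final`` selects the head: softmax
    over ``n_classes`` channels (cut regions) or sigmoid over one channel
    (binary pelvis mask).
    """

    n_classes: int = 5
    base_filters: int = 16
    depth: int = 5
    final: str = "softmax"
    epochs: int = 40
    lr_schedule: tuple = ((0, 10, 1e-4), (10, 40, 1e-5))
    class_weights: tuple = DEFAULT_CUT_WEIGHTS
    dice_alpha: float = 0.5
    grid_shape: tuple[int, int, int] = (128, 128, 128)

    def __post_init__(self) -> None:
        if self.final not in ("softmax", "sigmoid"):
            raise MisuseError("final must be 'softmax' or 'sigmoid'")
        if self.final == "softmax" and len(self.class_weights) != self.n_classes:
            raise MisuseError("class_weights length must equal n_classes")
        covered = 0
        for e0, e1, lr in self.lr_schedule:
            if e0 != covered or e1 <= e0 or lr <= 0:
                raise MisuseError("lr_schedule must tile [0, epochs) with positive rates")
            covered = e1
        if covered < self.epochs:
            raise MisuseError("lr_schedule does not cover all epochs")

    def learning_rate(self, epoch: int) -> float:
        for e0, e1, lr in self.lr_schedule:
            if e0 <= epoch < e1:
                return lr
        return self.lr_schedule[-1][2]

    @classmethod
    def cut_default(cls, grid: int = 128, epochs: int = 40) -> "SegmenterSpec":
        """Multi-label cut-region segmenter (5 channels, WCCE loss)."""
        sched = ((0, min(10, epochs), 1e-4),) + (
            ((min(10, epochs), epochs, 1e-5),) if epochs > 10 else ())
        return cls(n_classes=5, final="softmax", epochs=epochs, lr_schedule=sched,
                   grid_shape=(grid,) * 3)

    @classmethod
    def pelvis_default(cls, grid: int = 128, epochs: int = 40) -> "SegmenterSpec":
        """Binary pelvis-mask segmenter (sigmoid head, Dice-CE loss)."""
        bounds = [0, 20, 30, 40]
        rates = [1e-4, 1e-5, 1e-6]
        sched, covered = [], 0
        for b0, b1, lr in zip(bounds[:-1], bounds[1:], rates):
            if covered >= epochs:
                break
            sched.append((covered, min(b1, epochs), lr))
            covered = min(b1, epochs)
        if covered < epochs:
            sched.append((covered, epochs, rates[-1]))
        return cls(n_classes=1, final="sigmoid", class_weights=(1.0,),
                   epochs=epochs, lr_schedule=tuple(sched), grid_shape=(grid,) * 3)


class TrainedSegmenter:
    """Handle returned by :func:`train_segmenter`; usable as a backend."""

    def __init__(self, net: UNet3D, spec: SegmenterSpec, loss_trace: list[float]):
        self.net = net
        self.spec = spec
        self.loss_trace = loss_trace

    def predict_probs(self, vol: Volume) -> np.ndarray:
        return self.net.forward(vol.values.astype(np.float32))

    def predict(self, vol: Volume) -> LabelVolume:
        """Argmax labels (softmax) or 0/1 foreground (sigmoid)."""
        probs = self.predict_probs(vol)
        if self.spec.final == "softmax":
            labels = probs.argmax(axis=-1).astype(np.int16)
        else:
            labels = (probs[..., 0] > 0.5).astype(np.int16)
        return LabelVolume(labels, vol.spacing.copy(), vol.origin.copy(), vol.axes.copy())


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes, dtype=np.float32)[labels.astype(int)]


def train_segmenter(spec: SegmenterSpec, cases, seed: int = 0) -> TrainedSegmenter:
    """Train the U-Net on (image, labels) pairs; deterministic under seed.

    Images are expected pre-processed (cropped, normalized, resampled to
    ``spec.grid_shape``); labels are integer label volumes (or binary masks
    for the sigmoid head).
    """
    cases = list(cases)
    if len(cases) < 2:
        raise MisuseError("training requires at least 2 cases")
    for img, lab in cases:
        if img.shape != tuple(spec.grid_shape) or lab.shape != tuple(spec.grid_shape):
            raise MisuseError(
                f"case shapes {img.shape}/{lab.shape} do not match spec grid "
                f"{tuple(spec.grid_shape)}")

    rng = np.random.default_rng(seed)
    net = UNet3D(n_classes=spec.n_classes, base_filters=spec.base_filters,
                 depth=spec.depth, final=spec.final,
                 seed=int(rng.integers(2 ** 31)))
    opt = Adam(net)
    weights = np.asarray(spec.class_weights, dtype=np.float32)

    images = [np.asarray(img.values, dtype=np.float32) for img, _ in cases]
    if spec.final == "softmax":
        targets = [_one_hot(lab.values, spec.n_classes) for _, lab in cases]
    else:
        targets = [(lab.values > 0).astype(np.float32)[..., None] for _, lab in cases]

    trace: list[float] = []
    for epoch in range(spec.epochs):
        lr = spec.learning_rate(epoch)
        order = rng.permutation(len(cases))
        losses = []
        for ci in order:
            probs = net.forward(images[ci])
            t = targets[ci]
            if spec.final == "softmax":
                losses.append(wcce_loss(ClassProbabilities(t, probs, weights)))
                g = _wcce_grad_logits(t, probs, weights)
            else:
                losses.append(dice_ce_loss(probs, t, spec.dice_alpha))
                g = _dice_ce_grad_logits(t, probs, spec.dice_alpha)
            net.backward(g)
            opt.step(lr)
        trace.append(float(np.mean(losses)))
    return TrainedSegmenter(net, spec, trace)


# -- backends + plane fitting ----------------------------------------------


class OracleSegmenter:
    """Replays ground-truth labels (phantom truth) as a segmentation backend."""

    def __init__(self, labels: LabelVolume):
        self.labels = labels

    def predict(self, vol: Volume) -> LabelVolume:
        if vol.shape != self.labels.shape:
            raise MisuseError(
                f"oracle labels shape {self.labels.shape} does not match input {vol.shape}")
        return self.labels


def segment_cut_regions(post_ct: Volume, backend) -> LabelVolume:
    """Per-voxel osteotomy labels 1..4 (0 = background) from a backend.

    ``backend`` is any object with ``predict(Volume) -> LabelVolume``
    (an :class:`OracleSegmenter` or a :class:`TrainedSegmenter`).
    """
    if not hasattr(backend, "predict"):
        raise MisuseError("backend must expose predict(Volume) -> LabelVolume "
                          "(did you forget to train the network?)")
    labels = backend.predict(post_ct)
    if np.any(labels.values > 4):
        raise MisuseError("cut-region labels must lie in {0,1,2,3,4}")
    return labels


def fit_plane(points) -> Plane:
    """PCA plane fit: centroid as center, smallest-eigenvalue eigenvector
    of the point covariance as the (sign-unresolved) normal."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise MisuseError("points must be an (n, 3) array")
    if len(pts) < 3:
        raise DegenerateInputError("plane fit needs at least 3 points")
    center = pts.mean(axis=0)
    cov = (pts - center).T @ (pts - center) / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 1e-12 * max(evals[2], 1.0):
        raise DegenerateInputError("points are (nearly) collinear; plane undefined")
    return Plane(center=center, normal=evecs[:, 0])


@dataclass
class PlaneDetectionResult:
    """Per-osteotomy plane fits; ``planes[j]`` is None where fitting failed."""

    planes: list  # list[Plane | None], index j <-> cut label j+1
    failed: list[bool] = field(default_factory=lambda: [False] * 4)
    voxel_counts: list[int] = field(default_factory=lambda: [0] * 4)

    @property
    def all_ok(self) -> bool:
        return not any(self.failed)


def detect_planes(post_ct: Volume, backend) -> PlaneDetectionResult:
    """Segment cut regions and fit one plane per region (labels 1..4).

    Empty or degenerate regions are flagged as failed; the remaining
    planes are still returned.  Fitting operates on world-mm voxel
    centers, so results are invariant to anisotropic voxel spacing.
    """
    labels = segment_cut_regions(post_ct, backend)
    planes, failed, counts = [], [], []
    for j in range(1, 5):
        mask = labels.values == j
        counts.append(int(mask.sum()))
        try:
            pts = labels.voxel_centers_world(mask)
            planes.append(fit_plane(pts))
            failed.append(False)
        except DegenerateInputError:
            planes.append(None)
            failed.append(True)
    return PlaneDetectionResult(planes=planes, failed=failed, voxel_counts=counts)
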