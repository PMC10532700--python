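"""Outcome-comparison geometry and error metrics.

Implements the quantitative comparison used to judge an automatic
evaluation against a reference (manual or ground-truth) one: osteotomy
landmark points on the bone surface, their in-plane connecting vectors
and 2D angles, plane-normal angles, registration mean absolute error over
corresponding surface points, Dice overlap, and per-screw head/axis
errors — emitted as a serializable report.

Landmark semantics (plane 1 = supra-acetabular, 2 = retro-acetabular,
3 = ischial, 4 = pubic):

* P1: most superior surface point on cut plane 1,
* P2: most medial point on the intersection line of planes 1 and 2,
* P3: most medial point on the intersection line of planes 2 and 3,
* P4: most anterior surface point on cut plane 3,
* P5: most posterior surface point on cut plane 4.

P1..P4 are projected onto their best-fit plane PL; the connecting vectors
V1..V3 between consecutive projected points give the 2D angles
SR = angle(V1, V2) and RI = angle(V2, V3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cuts import fit_plane
from .errors import DetectionFailure, MisuseError
from .geometry import Plane, RigidTransform, angle_between_deg, unit
from .volume import LabelVolume


@dataclass
class AnatomicalAxes:
    """Configurable anatomical direction convention (unit world vectors)."""

    left: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    posterior: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    superior: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.left = unit(self.left)
        self.posterior = unit(self.posterior)
        self.superior = unit(self.superior)

    @property
    def anterior(self) -> np.ndarray:
        return -self.posterior


def surface_points(mask: LabelVolume) -> np.ndarray:
    """World centers of the one-voxel-thick boundary of a binary mask."""
    fg = mask.values > 0
    surf = fg & ~ndimage.binary_erosion(fg)
    return mask.voxel_centers_world(surf)


# -- landmarks --------------------------------------------------------------


@dataclass
class OsteotomyLandmarks:
    points: dict          # {"P1": array, ..., "P5": array}; failed -> None
    failed: list[str]     # names of landmarks that could not be computed

    def ok(self) -> bool:
        return not self.failed


def _surface_on_plane(surface: np.ndarray, plane: Plane, tol: float) -> np.ndarray:
    return surface[np.abs(plane.signed_distance(surface)) <= tol]


def _extremal(points: np.ndarray, direction: np.ndarray):
    if len(points) == 0:
        return None
    return points[int(np.argmax(points @ direction))]


def _plane_intersection_line(a: Plane, b: Plane):
    """(point, unit direction) of the intersection line of two planes."""
    d = np.cross(a.normal, b.normal)
    n = np.linalg.norm(d)
    if n < 1e-3:
        raise DetectionFailure("cut planes are near-parallel; intersection undefined")
    d = d / n
    # solve for the point closest to the origin satisfying both planes
    A = np.stack([a.normal, b.normal, d])
    rhs = np.array([a.normal @ a.center, b.normal @ b.center, 0.0])
    return np.linalg.solve(A, rhs), d


def _clip_line_to_box(point, direction, lo, hi):
    """Parameter interval of the line inside an axis-aligned box."""
    t0, t1 = -np.inf, np.inf
    for ax in range(3):
        if abs(direction[ax]) < 1e-12:
            if not (lo[ax] - 1e-9 <= point[ax] <= hi[ax] + 1e-9):
                return None
            continue
        ta = (lo[ax] - point[ax]) / direction[ax]
        tb = (hi[ax] - point[ax]) / direction[ax]
        t0, t1 = max(t0, min(ta, tb)), min(t1, max(ta, tb))
    return (t0, t1) if t0 <= t1 else None


def _most_medial_on_line(point, direction, surface, axes: AnatomicalAxes):
    """Point on the (box-clipped) line minimizing |lateral offset| from the
    surface's midsagittal plane."""
    lo, hi = surface.min(axis=0), surface.max(axis=0)
    interval = _clip_line_to_box(point, direction, lo, hi)
    if interval is None:
        raise DetectionFailure("intersection line misses the bone region")
    x_mid = float(surface.mean(axis=0) @ axes.left)
    f0 = float(point @ axes.left) - x_mid
    df = float(direction @ axes.left)
    candidates = list(interval)
    if abs(df) > 1e-12:
        t_zero = -f0 / df
        if interval[0] <= t_zero <= interval[1]:
            candidates.append(t_zero)
    elif abs(f0) < 1e-9:
        raise DetectionFailure("medial extremum degenerate: line parallel to midplane")
    best = min(candidates, key=lambda t: abs(f0 + t * df))
    return point + best * direction


def landmark_points(planes: list[Plane], surface: np.ndarray,
                    axes: AnatomicalAxes | None = None,
                    tol: float | None = None) -> OsteotomyLandmarks:
    """Compute P1..P5 from four oriented cut planes and a bone surface.

    ``tol`` is the surface-on-plane tolerance band (defaults to half the
    bounding voxel diagonal of a 1 mm grid, 0.87 mm).
    """
    axes = axes or AnatomicalAxes()
    surface = np.asarray(surface, dtype=float)
    if len(surface) == 0:
        raise MisuseError("surface point set is empty")
    if len(planes) != 4:
        raise MisuseError("landmark_points expects exactly 4 planes")
    tol = tol if tol is not None else np.sqrt(3.0) / 2.0

    points: dict = {}
    failed: list[str] = []

    def on_surface(name, plane, direction):
        p = _extremal(_surface_on_plane(surface, plane, tol), direction)
        if p is None:
            failed.append(name)
            points[name] = None
        else:
            points[name] = p

    on_surface("P1", planes[0], axes.superior)
    for name, (ia, ib) in (("P2", (0, 1)), ("P3", (1, 2))):
        try:
            pt, d = _plane_intersection_line(planes[ia], planes[ib])
            points[name] = _most_medial_on_line(pt, d, surface, axes)
        except DetectionFailure:
            failed.append(name)
            points[name] = None
    on_surface("P4", planes[2], axes.anterior)
    on_surface("P5", planes[3], axes.posterior)
    return OsteotomyLandmarks(points=points, failed=failed)


# -- projected 2D angles ----------------------------------------------------


@dataclass
class ProjectedAngles:
    plane: Plane                  # best-fit plane PL of P1..P4
    vectors: list[np.ndarray]     # V1..V3 between consecutive projected points
    sr: float                     # angle(V1, V2), degrees
    ri: float                     # angle(V2, V3), degrees


def projected_angles(p1, p2, p3, p4, plane: Plane | None = None) -> ProjectedAngles:
    """Project P1..P4 onto their best-fit plane and compute the in-plane
    connecting vectors and the two 2D angles SR and RI."""
    pts = np.array([p1, p2, p3, p4], dtype=float)
    pl = plane or fit_plane(pts)
    proj = pl.project(pts)
    vectors = [proj[i + 1] - proj[i] for i in range(3)]
    for v in vectors:
        if np.linalg.norm(v) < 1e-12:
            raise DetectionFailure("zero-length connecting vector; angle undefined")
    return ProjectedAngles(
        plane=pl, vectors=vectors,
        sr=angle_between_deg(vectors[0], vectors[1]),
        ri=angle_between_deg(vectors[1], vectors[2]),
    )


def normal_angle(n_a, n_b) -> float:
    """Sign-agnostic angle between two plane normals, degrees in [0, 90]."""
    d = abs(float(unit(n_a) @ unit(n_b)))
    return float(np.degrees(np.arccos(np.clip(d, 0.0, 1.0))))


# -- registration + overlap metrics -----------------------------------------


def registration_errors(points, t_a: RigidTransform, t_b: RigidTransform) -> float:
    """Mean absolute error (mm): mean Euclidean distance between the two
    transforms' images of the same surface points."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise MisuseError("registration_errors requires a non-empty point set")
    return float(np.linalg.norm(t_a.apply(pts) - t_b.apply(pts), axis=1).mean())


def dice_coefficient(a: LabelVolume, b: LabelVolume) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two binary masks."""
    if a.shape != b.shape:
        raise MisuseError("dice_coefficient requires a common grid")
    fa, fb = a.values > 0, b.values > 0
    denom = int(fa.sum()) + int(fb.sum())
    if denom == 0:
        raise MisuseError("dice undefined: both masks are empty")
    return 2.0 * int((fa & fb).sum()) / denom


# -- screw comparison -------------------------------------------------------


def match_screws(auto_entries: np.ndarray, ref_entries: np.ndarray,
                 gate_mm: float = 10.0) -> list[tuple[int, int]]:
    """Greedy mutual-nearest matching of entry points within a gate."""
    auto_entries = np.asarray(auto_entries, dtype=float).reshape(-1, 3)
    ref_entries = np.asarray(ref_entries, dtype=float).reshape(-1, 3)
    if len(auto_entries) == 0 or len(ref_entries) == 0:
        return []
    dist = np.linalg.norm(auto_entries[:, None] - ref_entries[None, :], axis=2)
    pairs = []
    used_a, used_r = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    for ia, ir in order:
        if dist[ia, ir] > gate_mm:
            break
        if ia in used_a or ir in used_r:
            continue
        # mutual-nearest among unused
        if (dist[ia, [r for r in range(dist.shape[1]) if r not in used_r]].min()
                < dist[ia, ir] - 1e-12):
            continue
        pairs.append((int(ia), int(ir)))
        used_a.add(ia)
        used_r.add(ir)
    return pairs


def screw_errors(auto, reference, gate_mm: float = 10.0) -> dict:
    """Per-screw head-center distance (mm) and sign-agnostic axis angle
    (degrees) for matched pairs; unmatched detections listed separately.

    ``auto`` is a list of :class:`~postop3d.screws.ScrewDetection`;
    ``reference`` any objects with ``entry_point`` and ``direction``.
    """
    a_entries = np.array([np.asarray(d.entry_point) for d in auto]).reshape(-1, 3)
    r_entries = np.array([np.asarray(s.entry_point) for s in reference]).reshape(-1, 3)
    pairs = match_screws(a_entries, r_entries, gate_mm)
    per_screw = []
    for ia, ir in pairs:
        head = float(np.linalg.norm(a_entries[ia] - r_entries[ir]))
        axis = normal_angle(auto[ia].direction, reference[ir].direction)
        per_screw.append({"auto": ia, "ref": ir, "head_mm": head, "axis_deg": axis})
    matched_a = {p[0] for p in pairs}
    matched_r = {p[1] for p in pairs}
    return {
        "matched": per_screw,
        "unmatched_auto": [i for i in range(len(auto)) if i not in matched_a],
        "unmatched_ref": [i for i in range(len(reference)) if i not in matched_r],
        "mean_head_mm": (float(np.mean([p["head_mm"] for p in per_screw]))
                         if per_screw else None),
        "mean_axis_deg": (float(np.mean([p["axis_deg"] for p in per_screw]))
                          if per_screw else None),
    }


# -- report -----------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Structured comparison of an automatic evaluation to a reference."""

    plane_normal_angles_deg: list = field(default_factory=list)
    plane_center_offsets_mm: list = field(default_factory=list)
    landmark_distances_mm: dict = field(default_factory=dict)
    vector_angles_deg: dict = field(default_factory=dict)
    sr_deviation_deg: float | None = None
    ri_deviation_deg: float | None = None
    pubic_normal_angle_deg: float | None = None
    err_t1_mm: float | None = None
    err_t2_mm: float | None = None
    err_t12_mm: float | None = None
    dice_auto: float | None = None
    dice_reference: float | None = None
    dice_difference: float | None = None
    screws: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x
        return {k: conv(v) for k, v in self.__dict__.items()}

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def compare_solutions(planes_auto: list[Plane], planes_ref: list[Plane],
                      surface: np.ndarray,
                      axes: AnatomicalAxes | None = None,
                      tol: float | None = None) -> EvaluationReport:
    """Cut-detection comparison of two four-plane solutions on one surface:
    per-plane normal angles and center offsets, landmark distances,
    in-plane vector angles, SR/RI deviations and the pubic normal angle."""
    axes = axes or AnatomicalAxes()
    rep = EvaluationReport()
    for pa, pr in zip(planes_auto, planes_ref):
        rep.plane_normal_angles_deg.append(normal_angle(pa.normal, pr.normal))
        rep.plane_center_offsets_mm.append(abs(float(pr.signed_distance(pa.center))))
    rep.pubic_normal_angle_deg = normal_angle(planes_auto[3].normal,
                                              planes_ref[3].normal)

    lm_a = landmark_points(planes_auto, surface, axes, tol)
    lm_r = landmark_points(planes_ref, surface, axes, tol)
    for name in ("P1", "P2", "P3", "P4", "P5"):
        a, r = lm_a.points.get(name), lm_r.points.get(name)
        if a is not None and r is not None:
            rep.landmark_distances_mm[name] = float(np.linalg.norm(a - r))
    if all(lm.points.get(n) is not None for lm in (lm_a, lm_r)
           for n in ("P1", "P2", "P3", "P4")):
        ang_a = projected_angles(*(lm_a.points[n] for n in ("P1", "P2", "P3", "P4")))
        ang_r = projected_angles(*(lm_r.points[n] for n in ("P1", "P2", "P3", "P4")))
        for k in range(3):
            rep.vector_angles_deg[f"V{k + 1}"] = angle_between_deg(
                ang_a.vectors[k], ang_r.vectors[k])
        rep.sr_deviation_deg = abs(ang_a.sr - ang_r.sr)
        rep.ri_deviation_deg = abs(ang_a.ri - ang_r.ri)
    return rep
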