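"""Screw implant quantification.

Three steps: (1) threshold the postoperative CT at a metal Hounsfield
level (> 2500 HU) to obtain the implant point cloud; (2) detect screw
center lines with an iterative 3D Hough transform — directions discretized
on a hemisphere of subdivided-icosahedron vertices, line anchors on a
``dx``-spaced grid in the plane through the origin orthogonal to each
direction, the global vote maximum refined by orthogonal least squares and
its supporting points removed before the next iteration; (3) walk from
each line's center of mass toward the screw head through the thresholded
mask with the Amanatides–Woo fast voxel traversal; the last foreground
voxel before the switch to background is the screw entry point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import MisuseError
from .geometry import unit
from .volume import LabelVolume, Volume

METAL_HU_THRESHOLD = 2500.0


@dataclass
class PointCloud:
    """World-mm voxel centers of above-threshold voxels."""

    points: np.ndarray            # (n, 3), may be empty
    source: Volume | None = None  # geometry reference

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise MisuseError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class HoughParams:
    """The three knobs of the line detector plus the direction granularity."""

    nlines: int = 6        # maximum number of lines to detect
    minvotes: int = 50     # minimum vote count to accept a line
    dx: float = 3.0        # anchor-grid step width, mm (also the
                           # point-to-line assignment radius)
    sphere_subdivisions: int = 4  # icosahedron subdivision level (~1.3 deg)

    def __post_init__(self) -> None:
        if self.nlines < 1:
            raise MisuseError("nlines must be >= 1")
        if self.minvotes < 2:
            raise MisuseError("minvotes must be >= 2")
        if self.dx <= 0:
            raise MisuseError("dx must be positive")


@dataclass
class HoughLine:
    n_points: int
    center: np.ndarray     # center of mass of the supporting points, mm
    direction: np.ndarray  # unit vector, canonical hemisphere


@dataclass
class ScrewDetection:
    """One detected screw: supporting points, axis and entry point."""

    n_points: int
    center: np.ndarray
    direction: np.ndarray    # unit vector, oriented toward the screw head
    entry_point: np.ndarray  # world mm
    out_of_field: bool = False

    def to_dict(self) -> dict:
        return {
            "n_points": int(self.n_points),
            "center": np.asarray(self.center).tolist(),
            "direction": np.asarray(self.direction).tolist(),
            "entry_point": np.asarray(self.entry_point).tolist(),
            "out_of_field": bool(self.out_of_field),
        }


# -- step 1: thresholding ---------------------------------------------------


def threshold_implants(post_ct: Volume, hu_threshold: float = METAL_HU_THRESHOLD
                       ) -> tuple[LabelVolume, PointCloud]:
    """Strictly-above-threshold metal mask and its voxel-center cloud."""
    sel = post_ct.values > hu_threshold
    mask = LabelVolume(sel.astype(np.int16), post_ct.spacing.copy(),
                       post_ct.origin.copy(), post_ct.axes.copy())
    cloud = PointCloud(post_ct.voxel_centers_world(sel) if sel.any()
                       else np.empty((0, 3)), source=post_ct)
    return mask, cloud


# -- step 2: iterative Hough ------------------------------------------------


def hemisphere_directions(subdivisions: int = 4) -> np.ndarray:
    """Unit directions on one hemisphere from a subdivided icosahedron."""
    verts = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0).vertices
    verts = np.asarray(verts, dtype=float)
    return np.array([v for v in verts if _on_canonical_hemisphere(v)])


def _on_canonical_hemisphere(v, eps: float = 1e-9) -> bool:
    if v[2] > eps:
        return True
    if v[2] < -eps:
        return False
    if v[1] > eps:
        return True
    if v[1] < -eps:
        return False
    return v[0] > eps


def canonical_direction(d: np.ndarray) -> np.ndarray:
    """Map a unit vector to the canonical hemisphere (sign-canonical)."""
    return d if _on_canonical_hemisphere(d) else -d


def _plane_basis(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane bases (u, v) for each direction."""
    d = directions
    helper = np.zeros_like(d)
    smallest = np.argmin(np.abs(d), axis=1)
    helper[np.arange(len(d)), smallest] = 1.0
    u = np.cross(d, helper)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    return u, v


def _line_distances(points: np.ndarray, anchor: np.ndarray, d: np.ndarray) -> np.ndarray:
    w = points - anchor
    along = w @ d
    return np.linalg.norm(w - np.outer(along, d), axis=1)


def _refit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal least-squares line: centroid + principal eigenvector."""
    c = points.mean(axis=0)
    cov = (points - c).T @ (points - c)
    _, evecs = np.linalg.eigh(cov)
    return c, canonical_direction(evecs[:, -1])


def hough_lines_3d(cloud: PointCloud, params: HoughParams | None = None) -> list[HoughLine]:
    """Iterative 3D Hough transform for lines in a point cloud.

    Per iteration the full voting array (directions x anchor cells) is
    rebuilt from the remaining points, the global maximum taken as the
    candidate line, the points within ``dx`` of it assigned and the line
    refined by orthogonal regression before the points are removed.  A
    line must reach ``minvotes`` both in the voting array and in assigned
    supporting points.  Detections are returned sorted by supporting-point
    count, at most ``nlines`` of them.
    """
    params = params or HoughParams()
    if len(cloud) == 0:
        raise MisuseError("hough_lines_3d requires a non-empty point cloud")

    dirs = hemisphere_directions(params.sphere_subdivisions)
    u, v = _plane_basis(dirs)

    centroid = cloud.points.mean(axis=0)
    pts = cloud.points - centroid
    radius = float(np.linalg.norm(pts, axis=1).max())
    half = int(np.ceil(radius / params.dx)) + 1
    n_cells = 2 * half + 1

    remaining = pts
    lines: list[HoughLine] = []
    while len(lines) < params.nlines and len(remaining) >= params.minvotes:
        # vote: each point votes for every direction's anchor cell
        xs = np.rint(remaining @ u.T / params.dx).astype(np.int64) + half
        ys = np.rint(remaining @ v.T / params.dx).astype(np.int64) + half
        flat = (np.arange(len(dirs))[None, :] * n_cells + xs) * n_cells + ys
        votes = np.bincount(flat.ravel(), minlength=len(dirs) * n_cells * n_cells)
        best = int(votes.argmax())
        if votes[best] < params.minvotes:
            break
        di, rem = divmod(best, n_cells * n_cells)
        ix, iy = divmod(rem, n_cells)
        d = dirs[di]
        anchor = ((ix - half) * params.dx) * u[di] + ((iy - half) * params.dx) * v[di]

        assigned = _line_distances(remaining, anchor, d) <= params.dx
        for _ in range(2):  # least-squares refinement + re-assignment
            if assigned.sum() < 2:
                break
            c, d = _refit_line(remaining[assigned])
            assigned = _line_distances(remaining, c, d) <= params.dx
        if assigned.sum() < params.minvotes:
            # candidate cell passed the vote floor but not the refined
            # support floor; drop its points to guarantee progress
            remaining = remaining[~assigned] if assigned.any() else remaining[:-1]
            continue
        support = remaining[assigned]
        c, d = _refit_line(support)
        lines.append(HoughLine(n_points=int(assigned.sum()),
                               center=c + centroid, direction=d))
        remaining = remaining[~assigned]

    return sorted(lines, key=lambda l: -l.n_points)


# -- head-direction disambiguation ------------------------------------------

_FALLBACK_AXES = (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0]),
                  np.array([1.0, 0.0, 0.0]))


def orient_toward_head(direction: np.ndarray, head_axis: np.ndarray) -> np.ndarray:
    """Flip ``direction`` so it points along ``head_axis`` (ties resolved
    by the remaining anatomical axes in a fixed order)."""
    direction = unit(direction)
    head_axis = unit(head_axis)
    for axis in (head_axis, *_FALLBACK_AXES):
        dot = float(direction @ axis)
        if abs(dot) > 1e-12:
            return direction if dot > 0 else -direction
    return direction  # pragma: no cover — unreachable for unit vectors


# -- step 3: fast voxel traversal -------------------------------------------


@dataclass
class EntryTrace:
    point: np.ndarray        # world center of the last foreground voxel
    out_of_field: bool       # ray left the grid while still in foreground
    visited: int = 0         # voxels crossed (each exactly once)


def trace_entry_point(mask: LabelVolume, start, direction) -> EntryTrace:
    """Amanatides–Woo traversal from ``start`` along ``direction``.

    Walks the voxel grid visiting each crossed voxel exactly once and
    returns the center of the last foreground voxel of the contiguous
    foreground run containing the start (the foreground-to-background
    switch point).  If the ray exits the grid while still in foreground,
    the last in-grid foreground voxel is returned with ``out_of_field``.
    """
    fg = mask.values > 0
    s = mask.voxel_from_world(np.asarray(start, dtype=float))
    d = (mask.axes.T @ unit(direction)) / mask.spacing  # index-space direction
    voxel = np.floor(s + 0.5).astype(int)
    shape = np.array(mask.shape)
    if np.any(voxel < 0) or np.any(voxel >= shape):
        raise MisuseError("start point lies outside the grid")
    if not fg[tuple(voxel)]:
        raise MisuseError("start point is not inside a foreground voxel")

    step = np.where(d > 0, 1, -1)
    with np.errstate(divide="ignore"):
        t_delta = np.where(d != 0, np.abs(1.0 / d), np.inf)
        # parameter t to the first boundary crossing per axis; voxel
        # boundaries sit at half-integer continuous indices
        next_boundary = voxel + np.where(d > 0, 0.5, -0.5)
        t_max = np.where(d != 0, (next_boundary - s) / d, np.inf)

    last_fg = voxel.copy()
    visited = 1
    while True:
        axis = int(np.argmin(t_max))
        voxel[axis] += step[axis]
        t_max[axis] += t_delta[axis]
        if voxel[axis] < 0 or voxel[axis] >= shape[axis]:
            return EntryTrace(mask.world_from_voxel(last_fg), True, visited)
        visited += 1
        if fg[tuple(voxel)]:
            last_fg = voxel.copy()
        else:
            return EntryTrace(mask.world_from_voxel(last_fg), False, visited)


# -- full pipeline ----------------------------------------------------------


def quantify_screws(post_ct: Volume, params: HoughParams | None = None,
                    head_axis=(0.0, 0.0, 1.0),
                    hu_threshold: float = METAL_HU_THRESHOLD) -> list[ScrewDetection]:
    """Threshold, detect center lines, orient them toward the head and
    trace each entry point; one detection per detected line."""
    params = params or HoughParams()
    mask, cloud = threshold_implants(post_ct, hu_threshold)
    if len(cloud) == 0:
        return []
    lines = hough_lines_3d(cloud, params)
    detections = []
    for line in lines:
        direction = orient_toward_head(line.direction, head_axis)
        start = line.center
        start_voxel = np.floor(post_ct.voxel_from_world(start) + 0.5).astype(int)
        if (np.any(start_voxel < 0) or np.any(start_voxel >= np.array(mask.shape))
                or not mask.values[tuple(start_voxel)]):
            # center of mass fell off the metal mask (e.g. between thread
            # voxels); snap to the nearest cloud point on the line
            dists = np.linalg.norm(cloud.points - start, axis=1)
            start = cloud.points[int(np.argmin(dists))]
        trace = trace_entry_point(mask, start, direction)
        detections.append(ScrewDetection(
            n_points=line.n_points, center=line.center, direction=direction,
            entry_point=trace.point, out_of_field=trace.out_of_field))
    return detections
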