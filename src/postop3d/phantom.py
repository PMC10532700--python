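"""Synthetic pre/post CT pairs with full ground truth.

The phantom emulates the geometry a periacetabular-osteotomy evaluation
pipeline has to cope with: a smooth bone-like body (union of ellipsoids) on
a soft-tissue background, four cut planes isolating a closed fragment, the
fragment repositioned by a known rigid transform, callus-like labelled
slabs of elevated intensity at each cut interface, metal-density screw
capsules crossing from fixed bone into the fragment, and a whole-body
rigid offset between the pre and post scans (the patient never lies in the
scanner the same way twice).

Everything is rasterized analytically per voxel, so the ground truth
(planes, transforms, labels, screw axes) is exact up to voxel sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import MisuseError, PhantomGenerationError
from .geometry import Plane, RigidTransform, unit
from .volume import LabelVolume, Volume

PELVIS_LABEL = 5
CUT_LABELS = (1, 2, 3, 4)

# outward face directions of the fragment tetrahedron before jitter:
# plane 1 (supra-acetabular) superior, 2 (retro-acetabular) posterior,
# 3 (ischial) and 4 (pubic) inferior-anterior, in the package's default
# anatomical convention (+x left, +y posterior, +z superior).
_TETRA = np.array([
    [0.0, 0.0, 1.0],
    [0.0, 0.9428, -1 / 3],
    [-0.8165, -0.4714, -1 / 3],
    [0.8165, -0.4714, -1 / 3],
])


@dataclass
class PhantomConfig:
    """Generation parameters; the defaults define the study conditions."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: float = 1.0              # mm, isotropic
    bone_hu: float = 700.0
    soft_hu: float = 40.0
    metal_hu: float = 3000.0
    callus_hu_delta: float = 150.0
    texture_sd: float = 200.0         # HU, trabecular-like intensity structure
    noise_sd: float = 20.0            # HU
    n_screws: int = 4
    callus_thickness: float = 4.0     # mm, full slab width at each cut
    rotation_deg: tuple[float, float] = (5.0, 15.0)      # fragment motion
    translation_mm: tuple[float, float] = (3.0, 10.0)
    global_rotation_deg: tuple[float, float] = (2.0, 8.0)  # scanner offset
    global_translation_mm: tuple[float, float] = (1.0, 6.0)
    screw_radius: float = 2.0         # mm
    screw_length: tuple[float, float] = (40.0, 80.0)
    min_screw_spacing: float = 6.0    # mm, minimum inter-axis distance
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.metal_hu > 2500.0 > self.bone_hu > self.soft_hu):
            raise MisuseError("require metal_hu > 2500 > bone_hu > soft_hu")
        if self.noise_sd < 0:
            raise MisuseError("noise_sd must be >= 0")
        if self.n_screws < 0:
            raise MisuseError("n_screws must be >= 0")
        self.shape = tuple(int(n) for n in self.shape)


@dataclass
class ScrewTruth:
    """Ground-truth screw: axis points toward the head (entry) end."""

    direction: np.ndarray     # unit vector, toward head
    entry_point: np.ndarray   # capsule cap apex at the head end, mm
    tip_point: np.ndarray     # distal segment endpoint, mm
    length: float             # segment length, mm
    radius: float             # mm

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}


@dataclass
class PhantomTruth:
    """Complete ground truth for one generated case (post-frame geometry)."""

    planes: list[Plane]                   # 4 cut planes, post frame
    coarse_transform: RigidTransform      # whole-body pre -> post (CTpost_T_CTpre)
    fragment_transform: RigidTransform    # full fragment map pre -> post (Fpost_T_Fpre)
    fragment_label: LabelVolume           # post frame, binary
    cut_labels: LabelVolume               # post frame, labels 1..4
    screws: list[ScrewTruth]
    seed: int
    pre_bone_label: LabelVolume = None    # pre frame pelvis mask (oracle)
    post_bone_label: LabelVolume = None   # post frame pelvis mask (oracle)
    pre_fragment_label: LabelVolume = None  # fragment in the pre frame

    @property
    def fine_transform(self) -> RigidTransform:
        """Residual fragment motion after coarse alignment
        (``fragment_transform ∘ coarse_transform⁻¹``)."""
        return self.fragment_transform.compose(self.coarse_transform.inverse())

    def to_dict(self) -> dict:
        return {
            "planes": [p.to_dict() for p in self.planes],
            "coarse_transform": self.coarse_transform.to_dict(),
            "fragment_transform": self.fragment_transform.to_dict(),
            "screws": [s.to_dict() for s in self.screws],
            "seed": self.seed,
        }


# -- analytic scene pieces --------------------------------------------------


def _sample_rotation(rng: np.random.Generator, max_deg: float) -> RigidTransform:
    axis = unit(rng.normal(size=3))
    angle = rng.uniform(0, max_deg)
    return RigidTransform.from_axis_angle(axis, angle)


def _sample_rigid(rng, rot_range, trans_range, center) -> RigidTransform:
    axis = unit(rng.normal(size=3))
    angle = rng.uniform(*rot_range)
    t = unit(rng.normal(size=3)) * rng.uniform(*trans_range)
    return RigidTransform.from_axis_angle(axis, angle, center=center, translation=t)


def _body_ellipsoids(rng, center: np.ndarray, scale: float
                     ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Union-of-ellipsoids bone body; geometry scales with the field of
    view (``scale`` = 1 for the default 96 mm extent)."""
    jit = lambda s: rng.uniform(-s, s, size=3) * scale  # noqa: E731
    s = scale
    return [
        (center + np.array([0, 0, 2]) * s + jit(2.0), np.array([32, 30, 28]) * s + jit(2.0)),
        (center + np.array([6, -6, -12]) * s + jit(2.0), np.array([24, 22, 20]) * s + jit(2.0)),
        (center + np.array([-8, 6, 10]) * s + jit(2.0), np.array([22, 24, 20]) * s + jit(2.0)),
    ]


def _inside_body(points: np.ndarray, ells) -> np.ndarray:
    inside = np.zeros(len(points), dtype=bool)
    for c, s in ells:
        q = (points - c) / s
        inside |= np.einsum("ij,ij->i", q, q) <= 1.0
    return inside


def _plane_dots(points: np.ndarray, planes: list[Plane]) -> np.ndarray:
    """(N, 4) signed distances to each plane along its (inward) normal."""
    return np.stack([p.signed_distance(points) for p in planes], axis=1)


def _fragment_region(points, ells, planes) -> np.ndarray:
    d = _plane_dots(points, planes)
    return _inside_body(points, ells) & np.all(d > 0.0, axis=1)


class _Texture:
    """Smooth trabecular-like intensity field: a sum of random 3D cosines.

    The field is a function of *anatomy* coordinates, so when the fragment
    moves the texture moves with it — this is what gives an intensity-based
    registration something to lock onto inside otherwise homogeneous bone.
    """

    def __init__(self, rng: np.random.Generator, sd: float, n_waves: int = 40):
        dirs = rng.normal(size=(n_waves, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        wavelength = rng.uniform(10.0, 40.0, size=n_waves)  # mm
        self.k = dirs * (2 * np.pi / wavelength)[:, None]
        self.phase = rng.uniform(0, 2 * np.pi, size=n_waves)
        amp = rng.uniform(0.5, 1.0, size=n_waves)
        # normalize so the field variance is sd^2 (each cosine has var a^2/2)
        self.amp = amp * sd / np.sqrt(np.sum(amp ** 2) / 2.0)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        out = np.zeros(len(points), dtype=np.float32)
        for k, ph, a in zip(self.k, self.phase, self.amp):
            out += (a * np.cos(points @ k + ph)).astype(np.float32)
        return out


def _cut_label_field(points, ells, planes, dots, thickness: float) -> np.ndarray:
    """Callus labels 1..4: each cut interface patch extruded symmetrically
    by ``thickness/2`` along its plane normal.

    The in-plane patch (body interior restricted to the other three
    half-spaces) is evaluated at the *projection* of each point onto the
    plane, so the labelled region is an exact symmetric prism around the
    cut: its centroid lies on the plane and its smallest principal axis is
    the plane normal, up to voxel sampling.
    """
    half_t = thickness / 2.0
    labels = np.zeros(len(points), dtype=np.int16)
    for j in range(3, -1, -1):
        near = np.abs(dots[:, j]) <= half_t
        proj = points[near] - np.outer(dots[near, j], planes[j].normal)
        patch = _inside_body(proj, ells)
        for k in range(4):
            if k != j:
                patch &= planes[k].signed_distance(proj) > 0.0
        sel = np.flatnonzero(near)[patch]
        labels[sel] = j + 1
    return labels


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 3D segments."""
    u, v, w = p1 - p0, q1 - q0, p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    s = np.clip((b * e - c * d) / denom, 0, 1) if denom > 1e-12 else 0.0
    t = np.clip((a * s + e) / c, 0, 1) if c > 1e-12 else 0.0
    s = np.clip((b * t - d) / a, 0, 1) if a > 1e-12 else s
    return float(np.linalg.norm(w + s * u - t * v))


def _place_screws(rng, cfg: PhantomConfig, frag_center_post: np.ndarray,
                  extent: np.ndarray, scale: float = 1.0) -> list[ScrewTruth]:
    screws: list[ScrewTruth] = []
    for _ in range(200):
        if len(screws) == cfg.n_screws:
            break
        # axis toward the head: within 25 degrees of superior (+z)
        polar = np.radians(rng.uniform(0, 25))
        az = rng.uniform(0, 2 * np.pi)
        direction = np.array([
            np.sin(polar) * np.cos(az), np.sin(polar) * np.sin(az), np.cos(polar),
        ])
        tip = frag_center_post + np.array([rng.uniform(-9, 9), rng.uniform(-9, 9),
                                           rng.uniform(-6, 0)]) * scale
        # keep the head end inside the grid with margin
        max_len = (extent[2] - 8.0 - tip[2]) / direction[2]
        length = min(rng.uniform(*cfg.screw_length) * scale, max_len)
        if length < cfg.screw_length[0] * 0.6 * min(scale, 1.0):
            continue
        head = tip + length * direction
        if np.any(head < 6.0) or np.any(head > extent - 6.0):
            continue
        ok = all(
            _segment_distance(tip, head, s.tip_point,
                              s.tip_point + s.length * s.direction) >= cfg.min_screw_spacing
            for s in screws
        )
        if ok:
            screws.append(ScrewTruth(
                direction=direction,
                entry_point=head + cfg.screw_radius * direction,
                tip_point=tip, length=float(length), radius=cfg.screw_radius,
            ))
    if len(screws) < cfg.n_screws:
        raise PhantomGenerationError("could not place screws with the requested spacing")
    return screws


def _capsule_mask(points: np.ndarray, s: ScrewTruth) -> np.ndarray:
    head = s.tip_point + s.length * s.direction
    w = points - s.tip_point
    t = np.clip(w @ s.direction, 0.0, s.length)
    closest = s.tip_point + t[:, None] * s.direction
    return np.linalg.norm(points - closest, axis=1) <= s.radius


# -- generation -------------------------------------------------------------


def make_phantom(config: PhantomConfig) -> tuple[Volume, Volume, PhantomTruth]:
    """Generate a (pre, post, truth) triple; bit-identical under one seed."""
    root = np.random.SeedSequence(config.seed)
    rng_scene, rng_noise_pre, rng_noise_post = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    shape = np.array(config.shape)
    spacing = float(config.spacing)
    extent = shape * spacing
    center = extent / 2

    grid_idx = np.stack(
        np.meshgrid(*(np.arange(n) for n in config.shape), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pts = grid_idx * spacing  # world = index * spacing (origin 0, identity axes)

    scale = float(extent.min()) / 96.0   # scene geometry follows the field of view
    ells = _body_ellipsoids(rng_scene, center, scale)
    texture = _Texture(rng_scene, config.texture_sd) if config.texture_sd > 0 else None
    frag_center = (center + np.array([12.0, 2.0, -9.0]) * scale
                   + rng_scene.uniform(-2, 2, size=3) * scale)

    last_err = "no attempt made"
    for _attempt in range(20):
        # four cut planes: jittered tetrahedron of inward half-spaces around
        # the fragment center
        jitter = _sample_rotation(rng_scene, 10.0).rotation
        planes_pre = []
        for v in _TETRA:
            v_j = _sample_rotation(rng_scene, 5.0).rotation @ (jitter @ v)
            dist = rng_scene.uniform(12.0, 18.0) * scale
            planes_pre.append(Plane(center=frag_center + dist * v_j, normal=-v_j))

        local = _sample_rigid(rng_scene, config.rotation_deg, config.translation_mm,
                              center=frag_center)
        coarse = _sample_rigid(rng_scene, config.global_rotation_deg,
                               config.global_translation_mm, center=center)
        total = coarse.compose(local)

        ok, last_err, out = _rasterize(config, pts, grid_idx, shape, spacing, ells,
                                       planes_pre, coarse, total, frag_center,
                                       extent, texture, rng_scene,
                                       rng_noise_pre, rng_noise_post)
        if ok:
            return out
    raise PhantomGenerationError(
        f"failed to isolate a closed fragment after 20 plane draws: {last_err}")


def _rasterize(cfg, pts, grid_idx, shape, spacing, ells, planes_pre,
               coarse, total, frag_center, extent, texture, rng_scene,
               rng_noise_pre, rng_noise_post):
    n = len(pts)
    geom = dict(spacing=np.full(3, spacing), origin=np.zeros(3), axes=np.eye(3))

    body_pre = _inside_body(pts, ells)
    dots_pre = _plane_dots(pts, planes_pre)
    frag_pre = body_pre & np.all(dots_pre > 0.0, axis=1)

    if frag_pre.sum() < 300:
        return False, f"fragment too small ({int(frag_pre.sum())} voxels)", None
    frag_idx = grid_idx[frag_pre]
    if frag_idx.min() < 1 or np.any(frag_idx.max(axis=0) >= shape - 1):
        return False, "fragment touches the grid border", None

    cut_pre = _cut_label_field(pts, ells, planes_pre, dots_pre, cfg.callus_thickness)
    counts = [int((cut_pre == j).sum()) for j in CUT_LABELS]
    if min(counts) < 30:
        return False, f"cut region too small (voxel counts {counts})", None

    # --- pre image ---------------------------------------------------------
    pre_vals = np.full(n, cfg.soft_hu, dtype=np.float32)
    pre_vals[body_pre] = cfg.bone_hu
    if texture is not None:
        pre_vals[body_pre] += texture(pts[body_pre])
    if cfg.noise_sd > 0:
        pre_vals += rng_noise_pre.normal(0, cfg.noise_sd, size=n).astype(np.float32)

    # --- post image: pull back through the two transforms ------------------
    inv_coarse, inv_total = coarse.inverse(), total.inverse()
    y = inv_coarse.apply(pts)   # fixed-anatomy coordinates in the pre frame
    z = inv_total.apply(pts)    # fragment-material coordinates in the pre frame

    body_y = _inside_body(y, ells)
    dots_y = _plane_dots(y, planes_pre)
    fixed_post = body_y & ~np.all(dots_y > 0.0, axis=1)
    frag_post = _fragment_region(z, ells, planes_pre)

    cut_post = _cut_label_field(y, ells, planes_pre, dots_y, cfg.callus_thickness)

    post_vals = np.full(n, cfg.soft_hu, dtype=np.float32)
    post_vals[fixed_post] = cfg.bone_hu
    post_vals[cut_post > 0] = cfg.bone_hu + cfg.callus_hu_delta  # healing callus
    post_vals[frag_post] = cfg.bone_hu
    if texture is not None:
        # texture follows the anatomy: fixed bone and callus keep the
        # pre-frame field, fragment material carries its field along
        fixed_like = (fixed_post | (cut_post > 0)) & ~frag_post
        post_vals[fixed_like] += texture(y[fixed_like])
        post_vals[frag_post] += texture(z[frag_post])

    frag_center_post = total.apply(frag_center)
    scale = float(extent.min()) / 96.0
    try:
        screws = _place_screws(rng_scene, cfg, frag_center_post, extent, scale)
    except PhantomGenerationError as exc:
        return False, str(exc), None
    metal = np.zeros(n, dtype=bool)
    for s in screws:
        m = _capsule_mask(pts, s)
        if m.sum() < 50:
            return False, "screw rasterized to too few voxels", None
        metal |= m
    post_vals[metal] = cfg.metal_hu
    if cfg.noise_sd > 0:
        post_vals += rng_noise_post.normal(0, cfg.noise_sd, size=n).astype(np.float32)

    shp = tuple(int(v) for v in shape)
    pre = Volume(pre_vals.reshape(shp), **geom)
    post = Volume(post_vals.reshape(shp), **geom)

    planes_post = [
        Plane(coarse.apply(p.center), coarse.apply_vector(p.normal)) for p in planes_pre
    ]
    truth = PhantomTruth(
        planes=planes_post,
        coarse_transform=coarse,
        fragment_transform=total,
        fragment_label=LabelVolume(frag_post.reshape(shp).astype(np.int16), **geom),
        cut_labels=LabelVolume(cut_post.reshape(shp), **geom, label_set=CUT_LABELS),
        screws=screws,
        seed=cfg.seed,
        pre_bone_label=LabelVolume(
            (body_pre.reshape(shp) * PELVIS_LABEL).astype(np.int16), **geom),
        # the pelvis mask mirrors a threshold-based bone segmentation:
        # mineralized bone only — no immature callus, no metal
        post_bone_label=LabelVolume(
            ((((fixed_post | frag_post) & ~metal).reshape(shp))
             * PELVIS_LABEL).astype(np.int16), **geom),
        pre_fragment_label=LabelVolume(frag_pre.reshape(shp).astype(np.int16), **geom),
    )
    return True, "", (pre, post, truth)


# -- offline augmentation ---------------------------------------------------


def augment(vol: Volume, ops, seed: int, max_rotation_deg: float = 10.0,
            max_translation_mm: float = 10.0, flip_axis: int = 0) -> Volume:
    """Geometry-preserving training augmentation (flip / rotate / translate).

    Operates in index space (the grid metadata is unchanged), mirroring
    offline augmentation of network inputs.  Label volumes are warped with
    nearest-neighbour interpolation.  Deterministic under ``seed``.
    """
    from scipy import ndimage

    ops = list(ops)
    if not ops:
        raise MisuseError("augment requires a non-empty set of ops")
    bad = set(ops) - {"flip", "rotate", "translate"}
    if bad:
        raise MisuseError(f"unknown augmentation ops: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    is_labels = isinstance(vol, LabelVolume)
    order = 0 if is_labels else 1
    values = vol.values

    if "flip" in ops:
        values = np.flip(values, axis=flip_axis).copy()
    if "rotate" in ops or "translate" in ops:
        angle = rng.uniform(-max_rotation_deg, max_rotation_deg) if "rotate" in ops else 0.0
        shift = (rng.uniform(-max_translation_mm, max_translation_mm, size=3) / vol.spacing
                 if "translate" in ops else np.zeros(3))
        rot = RigidTransform.from_axis_angle(
            unit(rng.normal(size=3)), angle,
            center=(np.array(vol.shape) - 1) / 2.0, translation=shift)
        inv = rot.inverse()
        values = ndimage.affine_transform(
            values.astype(values.dtype if is_labels else float),
            inv.rotation, offset=inv.translation, order=order,
            mode="constant", cval=float(values.min()))
    if is_labels:
        return LabelVolume(values.astype(vol.values.dtype), vol.spacing.copy(),
                           vol.origin.copy(), vol.axes.copy(), label_set=vol.label_set)
    return Volume(values, vol.spacing.copy(), vol.origin.copy(), vol.axes.copy())
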