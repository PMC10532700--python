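"""Volume data model and geometry-aware raster operations.

A :class:`Volume` is a 3D scalar grid together with the affine mapping from
voxel indices to world millimetres::

    world = origin + axes @ (spacing * index)

Indices are 0-based and refer to voxel *centers* (the dominant
medical-imaging convention).  ``values`` is stored in (x, y, z) index order,
i.e. ``values[i, j, k]`` is the voxel whose continuous index is (i, j, k).
File I/O goes through SimpleITK, so NIfTI (.nii/.nii.gz), NRRD (.nrrd) and
MetaImage (.mha/.mhd) are supported with geometry taken from the headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import (
    DegenerateInputError,
    DimensionalityError,
    EmptyCropError,
    FormatError,
    MisuseError,
)

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd", ".mha", ".mhd")


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.shape != (3,):
        raise MisuseError(f"{name} must be a length-3 vector, got shape {v.shape}")
    return v


@dataclass
class Volume:
    """3D scalar grid (HU or labels) with world-space geometry.

    Parameters
    ----------
    values
        3D array, index order (x, y, z).
    spacing
        Per-axis voxel size in mm, all components > 0.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    axes
        3x3 direction matrix; column ``i`` is the unit world direction of
        index axis ``i``.  Must be orthonormal.
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise DimensionalityError(
                f"values must be a 3D array with positive dims, got shape {self.values.shape}"
            )
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise MisuseError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_vec3(self.origin, "origin")
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.shape != (3, 3):
            raise MisuseError("axes must be a 3x3 matrix")
        if np.max(np.abs(self.axes.T @ self.axes - np.eye(3))) > 1e-6:
            raise MisuseError("axes must be orthonormal")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def world_from_voxel(self, index) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to world mm."""
        idx = np.asarray(index, dtype=float)
        return self.origin + (idx * self.spacing) @ self.axes.T

    def voxel_from_world(self, world) -> np.ndarray:
        """Inverse of :meth:`world_from_voxel` (continuous indices)."""
        w = np.asarray(world, dtype=float)
        return ((w - self.origin) @ self.axes) / self.spacing

    def voxel_centers_world(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World mm centers of all voxels (or of ``mask``'s True voxels)."""
        if mask is None:
            idx = np.stack(
                np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"), axis=-1
            ).reshape(-1, 3)
        else:
            idx = np.argwhere(np.asarray(mask))
        return self.world_from_voxel(idx)

    # -- SimpleITK bridge ---------------------------------------------------

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.transpose(2, 1, 0)))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.axes.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        if img.GetDimension() != 3:
            raise DimensionalityError(f"expected a 3D image, got {img.GetDimension()}D")
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            values=values,
            spacing=np.array(img.GetSpacing()),
            origin=np.array(img.GetOrigin()),
            axes=np.array(img.GetDirection()).reshape(3, 3),
        )

    def same_grid_as(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.axes, other.axes, atol=atol)
        )

    def with_values(self, values: np.ndarray) -> "Volume":
        """Copy of this volume's geometry carrying new ``values``."""
        if values.shape != self.shape:
            raise MisuseError("replacement values must match the grid shape")
        return replace(self, values=values)


@dataclass
class LabelVolume(Volume):
    """Volume whose values are non-negative integer labels.

    Label semantics in this package: 0 = background, 1-4 = osteotomy cut
    regions (label i <-> cut plane i), 5 = pelvis bone when the volume is
    used as a binary registration mask.
    """

    label_set: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.values.dtype, np.integer):
            v = np.asarray(self.values)
            if not np.all(v == np.round(v)):
                raise MisuseError("LabelVolume values must be integers")
            self.values = v.astype(np.int16)
        if np.any(self.values < 0):
            raise MisuseError("labels must be non-negative")
        if self.label_set is not None:
            bad = set(np.unique(self.values)) - set(self.label_set) - {0}
            if bad:
                raise MisuseError(f"labels {sorted(bad)} outside declared set {self.label_set}")

    def binary(self, label: int | None = None) -> np.ndarray:
        """Boolean foreground mask (``values > 0`` or ``values == label``)."""
        return self.values > 0 if label is None else self.values == label


# -- I/O --------------------------------------------------------------------


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise FormatError(
            f"unsupported volume format '{path.name}'; use one of {_SUPPORTED_SUFFIXES}"
        )


def read_volume(path, labels: bool = False) -> Volume:
    """Read a NIfTI / NRRD / MetaImage volume with its header geometry."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps ITK read failures
        raise FormatError(f"could not read {path}: {exc}") from exc
    vol = Volume.from_sitk(img)
    if labels:
        return LabelVolume(vol.values, vol.spacing, vol.origin, vol.axes)
    return vol


def write_volume(vol: Volume, path) -> None:
    path = Path(path)
    _check_suffix(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(vol.to_sitk(), str(path), useCompression=path.name.endswith(".gz"))


# -- raster operations ------------------------------------------------------


def resample(vol: Volume, target_shape, interpolation: str = "linear") -> Volume:
    """Resample to ``target_shape`` voxels, preserving the physical extent.

    The field of view (outer voxel edges) is kept fixed in world space, so
    spacing rescales by ``old_shape / new_shape`` per axis.  ``interpolation``
    is ``"linear"`` (trilinear, for HU) or ``"nearest"`` (mandatory for
    label volumes).
    """
    target_shape = tuple(int(n) for n in np.asarray(target_shape).reshape(-1))
    if len(target_shape) != 3 or min(target_shape) < 1:
        raise MisuseError(f"target_shape must be 3 positive integers, got {target_shape}")
    if interpolation not in ("linear", "nearest"):
        raise MisuseError(f"unknown interpolation '{interpolation}'")
    is_labels = isinstance(vol, LabelVolume)
    if is_labels and interpolation != "nearest":
        raise MisuseError("label volumes must be resampled with nearest-neighbour")

    old_shape = np.array(vol.shape, dtype=float)
    new_shape = np.array(target_shape, dtype=float)
    ratio = old_shape / new_shape
    # voxel-center mapping that keeps the outer voxel edges fixed
    grids = np.meshgrid(*(np.arange(n) for n in target_shape), indexing="ij")
    coords = [(g + 0.5) * r - 0.5 for g, r in zip(grids, ratio)]
    order = 0 if interpolation == "nearest" else 1
    values = ndimage.map_coordinates(
        vol.values.astype(vol.values.dtype if is_labels else float),
        coords, order=order, mode="nearest",
    )
    new_spacing = vol.spacing * ratio
    new_origin = vol.origin + vol.axes @ (vol.spacing * (ratio - 1) / 2)
    if is_labels:
        return LabelVolume(values, new_spacing, new_origin, vol.axes.copy(),
                           label_set=vol.label_set)
    return Volume(values, new_spacing, new_origin, vol.axes.copy())


def crop_world(vol: Volume, center, half_extent) -> Volume:
    """Crop to the axis-aligned world box ``center ± half_extent`` (mm).

    Retains every voxel whose center lies inside the box (for rotated
    ``axes`` the minimal index-aligned bounding box of the region).  World
    coordinates of retained voxels are unchanged.
    """
    center = _as_vec3(center, "center")
    half_extent = _as_vec3(half_extent * np.ones(3) if np.isscalar(half_extent) else half_extent,
                           "half_extent")
    corners = center + np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    ) * half_extent
    idx = vol.voxel_from_world(corners)
    lo = np.ceil(idx.min(axis=0) - 1e-9).astype(int)
    hi = np.floor(idx.max(axis=0) + 1e-9).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(vol.shape) - 1)
    if np.any(lo > hi):
        raise EmptyCropError("crop box does not intersect the volume")
    values = vol.values[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1].copy()
    new_origin = vol.world_from_voxel(lo)
    if isinstance(vol, LabelVolume):
        return LabelVolume(values, vol.spacing.copy(), new_origin, vol.axes.copy(),
                           label_set=vol.label_set)
    return Volume(values, vol.spacing.copy(), new_origin, vol.axes.copy())


def normalize_intensity(vol: Volume) -> Volume:
    """Min-max rescale intensities to [0, 1]; geometry unchanged."""
    v = vol.values.astype(float)
    lo, hi = float(v.min()), float(v.max())
    if hi - lo <= 0:
        raise DegenerateInputError("cannot normalize a constant volume")
    return vol.with_values((v - lo) / (hi - lo))
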