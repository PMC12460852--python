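"""Volumes, binary masks, NIfTI I/O and grid resampling.

A :class:`VolumeImage` is a 3-D scalar lattice with physical geometry
(voxel spacing in mm, origin in mm, a 3x3 direction-cosine matrix).  A
:class:`MaskVolume` is a binary labelmap living on the same kind of grid.
All downstream mask algebra happens on the pre-recurrence anatomical grid,
so the central primitive here is resampling one grid onto another through
an affine world mapping, with linear interpolation for intensities and
nearest-neighbour (or linear + 0.5 threshold) for masks.

Conventions: voxel indices are 0-based; world coordinates follow the NIfTI
affine convention ``x_world = direction @ (spacing * index) + origin``.
Voxels that map outside the source field of view receive the fill value 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Raised when grids are incompatible or physically disjoint."""


class FormatError(ValueError):
    """Raised for malformed or unsupported image files."""


_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class GridGeometry:
    """Physical layout of a 3-D voxel lattice."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1, 0, 0, 0, 1, 0, 0, 0, 1)

    def __post_init__(self):
        if len(self.shape) != 3:
            raise GeometryError(f"grid must be 3-D, got shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        R = self.direction_matrix
        if np.linalg.norm(R.T @ R - np.eye(3)) >= _ORTHO_TOL:
            raise GeometryError("direction cosines are not orthonormal")

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (NIfTI convention)."""
        A = np.eye(4)
        A[:3, :3] = self.direction_matrix @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def center_world(self) -> np.ndarray:
        """World coordinates of the geometric grid centre."""
        c = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.index_to_world(c)[0]

    def same_grid(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    @staticmethod
    def from_affine(shape, affine: np.ndarray) -> "GridGeometry":
        M = np.asarray(affine, dtype=float)[:3, :3]
        spacing = np.linalg.norm(M, axis=0)
        direction = M / spacing
        return GridGeometry(
            shape=tuple(int(s) for s in shape),
            spacing=tuple(float(s) for s in spacing),
            origin=tuple(float(o) for o in np.asarray(affine)[:3, 3]),
            direction=tuple(direction.ravel()),
        )


@dataclass
class VolumeImage:
    """3-D scalar image with physical grid geometry and a unit label."""

    data: np.ndarray
    grid: GridGeometry
    units: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise GeometryError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def spacing(self):
        return self.grid.spacing

    @property
    def origin(self):
        return self.grid.origin

    def copy(self) -> "VolumeImage":
        return VolumeImage(self.data.copy(), self.grid, self.units)


@dataclass
class MaskVolume:
    """Binary labelmap on a :class:`GridGeometry`."""

    data: np.ndarray
    grid: GridGeometry

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise GeometryError(f"mask data must be 3-D, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0,1}}, found {uniq[:10]}")
        self.data = arr.astype(bool)
        if tuple(arr.shape) != tuple(self.grid.shape):
            raise GeometryError(
                f"data shape {arr.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def copy(self) -> "MaskVolume":
        return MaskVolume(self.data.copy(), self.grid)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path, units: str = "") -> VolumeImage:
    """Read a 3-D NIfTI-1 volume.

    Raises :class:`FormatError` for unreadable files and
    :class:`GeometryError` for non-3-D payloads.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except Exception as exc:  # nibabel raises several unrelated types
        if isinstance(exc, FileNotFoundError):
            raise
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3-D volume, got ndim={data.ndim}")
    grid = GridGeometry.from_affine(data.shape, img.affine)
    return VolumeImage(data, grid, units=units)


def write_volume(volume: VolumeImage, path) -> None:
    """Write as NIfTI-1, float32 for images."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.grid.affine)
    nib.save(img, str(path))


def read_mask(path) -> MaskVolume:
    vol = read_volume(path)
    return MaskVolume(vol.data > 0.5, vol.grid)


def write_mask(mask: MaskVolume, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling


def _grids_overlap(source: GridGeometry, target: GridGeometry) -> bool:
    """Cheap physical-extent overlap test on corner bounding boxes."""
    def bbox(g: GridGeometry):
        corners = np.array(
            [[i, j, k] for i in (0, g.shape[0] - 1)
             for j in (0, g.shape[1] - 1)
             for k in (0, g.shape[2] - 1)], dtype=float)
        w = g.index_to_world(corners)
        return w.min(axis=0), w.max(axis=0)

    lo_s, hi_s = bbox(source)
    lo_t, hi_t = bbox(target)
    # allow half-voxel slack at the faces
    pad = 0.5 * max(max(source.spacing), max(target.spacing))
    return bool(np.all(lo_t <= hi_s + pad) and np.all(hi_t >= lo_s - pad))


def resample_to_grid(
    volume: VolumeImage,
    target: GridGeometry,
    mode: str = "linear",
    world_map=None,
    fill: float = 0.0,
) -> VolumeImage:
    """Resample ``volume`` onto ``target``.

    ``mode`` is ``"linear"`` (intensities) or ``"nearest"`` (labels).
    ``world_map``, if given, maps target-world points to source-world points
    (used by the registration module to resample through a rigid transform);
    identity otherwise.  Voxels mapping outside the source get ``fill``.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    if world_map is None and not _grids_overlap(volume.grid, target):
        raise GeometryError("source and target grids have disjoint physical extents")

    if world_map is None and volume.grid.same_grid(target):
        return VolumeImage(volume.data.copy(), target, volume.units)

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in target.shape), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    world = target.index_to_world(idx)
    if world_map is not None:
        world = world_map(world)
    src_idx = volume.grid.world_to_index(world)
    coords = src_idx.T.reshape(3, *target.shape)
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float), coords, order=order,
        mode="constant", cval=fill)
    return VolumeImage(out, target, volume.units)


def resample_mask_to_grid(
    mask: MaskVolume, target: GridGeometry, world_map=None
) -> MaskVolume:
    """Mask resampling: linear interpolation of the indicator, cut at 0.5.

    The 0.5 threshold is unbiased for half-voxel shifts; voxels outside the
    source field of view are 0.
    """
    vol = VolumeImage(mask.data.astype(float), mask.grid)
    out = resample_to_grid(vol, target, mode="linear", world_map=world_map)
    return MaskVolume(out.data > 0.5, target)
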