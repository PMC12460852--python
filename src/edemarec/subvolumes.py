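"""Sub-volume construction: partitioning pre-recurrence edema.

After the post-recurrence tumor contour is brought onto the
pre-recurrence grid by the rigid transform, the edema splits into

* ``subedema_rec``    — edema overlapped by recurrent tumor, and
* ``subedema_no_rec`` — the remainder,

an exact voxel partition of the edema mask.  A case whose recurrent tumor
misses the edema entirely is flagged (``subedema_rec`` empty) and excluded
downstream, mirroring the inclusion criterion that recurrence must lie at
least partly within the original edema.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .imaging import GeometryError, GridGeometry, MaskVolume
from .registration import RigidTransform, apply_rigid_mask


@dataclass
class SubvolumeLabeling:
    subedema_rec: MaskVolume
    subedema_no_rec: MaskVolume
    edema: MaskVolume
    provenance: str = ""

    @property
    def rec_empty(self) -> bool:
        """True when recurrence does not touch the edema (excluded case)."""
        return self.subedema_rec.n_voxels == 0

    def check_partition(self) -> None:
        rec, norec, ede = (self.subedema_rec.data, self.subedema_no_rec.data,
                           self.edema.data)
        if np.any(rec & norec):
            raise AssertionError("subedema_rec and subedema_no_rec overlap")
        if not np.array_equal(rec | norec, ede):
            raise AssertionError("sub-volumes do not partition the edema")


def transform_mask(mask: MaskVolume, T: RigidTransform,
                   target: GridGeometry) -> MaskVolume:
    """Resample a mask through a rigid transform (linear + 0.5 cut)."""
    return apply_rigid_mask(mask, T, target)


def define_subvolumes(edema_pre: MaskVolume,
                      tumor_rec_on_pre_grid: MaskVolume,
                      provenance: str = "") -> SubvolumeLabeling:
    """Split edema into overlap-with-recurrence and remainder."""
    if not edema_pre.grid.same_grid(tumor_rec_on_pre_grid.grid):
        raise GeometryError("edema and recurrent-tumor masks are on different grids")
    if edema_pre.n_voxels == 0:
        raise ValueError("edema mask is empty")
    grid = edema_pre.grid
    rec = edema_pre.data & tumor_rec_on_pre_grid.data
    no_rec = edema_pre.data & ~tumor_rec_on_pre_grid.data
    labeling = SubvolumeLabeling(
        subedema_rec=MaskVolume(rec, grid),
        subedema_no_rec=MaskVolume(no_rec, grid),
        edema=edema_pre.copy(),
        provenance=provenance)
    labeling.check_partition()
    return labeling


def volume_mm3(mask: MaskVolume) -> float:
    """Voxel count times voxel volume."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3


def dice(a: MaskVolume | np.ndarray, b: MaskVolume | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    da = a.data if isinstance(a, MaskVolume) else np.asarray(a, dtype=bool)
    db = b.data if isinstance(b, MaskVolume) else np.asarray(b, dtype=bool)
    denom = int(da.sum()) + int(db.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((da & db).sum()) / denom


def write_labelmap(labeling: SubvolumeLabeling, path) -> None:
    """Export as one NIfTI labelmap: 1 = subedema_rec, 2 = subedema_no_rec."""
    codes = np.zeros(labeling.edema.grid.shape, dtype=np.uint8)
    codes[labeling.subedema_rec.data] = 1
    codes[labeling.subedema_no_rec.data] = 2
    img = nib.Nifti1Image(codes, labeling.edema.grid.affine)
    nib.save(img, str(path))
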