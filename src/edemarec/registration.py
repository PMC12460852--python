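"""Rigid transforms between imaging timepoints.

The analysis aligns the post-recurrence scan onto the pre-recurrence
anatomical grid with a 6-degree-of-freedom rigid transform (rotation +
translation about a centre).  This module represents such transforms,
applies them to volumes and masks, and can estimate one from a pair of
images by maximizing an intensity-similarity metric.  The pipeline also
accepts precomputed transforms, since in practice this step is often done
in an external viewer.

A transform maps *fixed-image (pre) world coordinates* to *moving-image
(post) world coordinates*:  ``y = R @ (x - c) + c + t``.  Resampling a
moving image onto the fixed grid therefore pulls intensities through the
forward map.  Rotations are parameterized internally as Euler angles
applied in Z-Y-X order about the centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import (GeometryError, GridGeometry, MaskVolume, VolumeImage,
                      resample_mask_to_grid, resample_to_grid)


class RegistrationError(RuntimeError):
    """Raised when transform estimation fails (e.g. empty image overlap)."""


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about ``center`` followed by translation, in world mm."""

    rotation: np.ndarray       # 3x3, orthonormal, det +1
    translation: np.ndarray    # mm
    center: np.ndarray         # mm

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float).reshape(3))
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=float).reshape(3))
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6 or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")

    @staticmethod
    def identity(center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3), np.asarray(center, float))

    @staticmethod
    def from_euler(angles_deg, translation, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Euler angles in degrees, applied in Z-Y-X order."""
        az, ay, ax = [np.deg2rad(a) for a in angles_deg[::-1]]  # input (rx, ry, rz)
        cz, sz = np.cos(az), np.sin(az)
        cy, sy = np.cos(ay), np.sin(ay)
        cx, sx = np.cos(ax), np.sin(ax)
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        return RigidTransform(Rz @ Ry @ Rx, translation, center)

    def euler_angles_deg(self) -> np.ndarray:
        """Recover (rx, ry, rz) in degrees from the Z-Y-X factorization."""
        R = self.rotation
        ry = np.arcsin(-R[2, 0])
        rz = np.arctan2(R[1, 0], R[0, 0])
        rx = np.arctan2(R[2, 1], R[2, 2])
        return np.rad2deg([rx, ry, rz])

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - self.center) @ self.rotation.T + self.center + self.translation

    def invert(self) -> "RigidTransform":
        Rinv = self.rotation.T
        # y = R(x-c)+c+t  =>  x = R^T(y-c)+c - R^T t
        return RigidTransform(Rinv, -Rinv @ self.translation, self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equal to applying ``other`` first, then self."""
        A, B = self.matrix4(), other.matrix4()
        M = A @ B
        R = M[:3, :3]
        # re-express about self.center
        c = self.center
        t = M[:3, 3] + R @ c - c
        return RigidTransform(R, t, c)

    def matrix4(self) -> np.ndarray:
        """4x4 homogeneous matrix of the world mapping."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation + self.center - self.rotation @ self.center
        return M

    @staticmethod
    def from_matrix4(M: np.ndarray, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        R = M[:3, :3]
        c = np.asarray(center, dtype=float)
        t = M[:3, 3] - c + R @ c
        return RigidTransform(R, t, c)


def save_transform(T: RigidTransform, path) -> None:
    """Serialize as a plain-text 4x4 homogeneous matrix (row per line)."""
    np.savetxt(str(path), T.matrix4(), fmt="%.17g",
               header="rigid transform, 4x4 homogeneous, world mm", comments="# ")


def load_transform(path, center=(0.0, 0.0, 0.0)) -> RigidTransform:
    M = np.loadtxt(str(path))
    if M.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {M.shape}")
    return RigidTransform.from_matrix4(M, center=center)


# ---------------------------------------------------------------------------
# Application


def apply_rigid(volume: VolumeImage, T: RigidTransform,
                target: GridGeometry, mode: str = "linear") -> VolumeImage:
    """Resample ``volume`` through ``T`` onto ``target``.

    ``T`` maps target-grid world points into the volume's world frame, so
    the output at target voxel x samples the input at T(x).
    """
    return resample_to_grid(volume, target, mode=mode, world_map=T.apply_points)


def apply_rigid_mask(mask: MaskVolume, T: RigidTransform,
                     target: GridGeometry) -> MaskVolume:
    """Mask variant: linear interpolation of the indicator, 0.5 cut."""
    return resample_mask_to_grid(mask, target, world_map=T.apply_points)


# ---------------------------------------------------------------------------
# Estimation

def _to_sitk(volume: VolumeImage):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.asarray(volume.data, dtype=np.float64).T.copy())
    img.SetSpacing(tuple(float(s) for s in volume.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.grid.origin))
    img.SetDirection(tuple(float(d) for d in volume.grid.direction))
    return img


def estimate_rigid(fixed: VolumeImage, moving: VolumeImage,
                   metric: str = "ncc",
                   shrink_factors=(4, 2, 1),
                   smoothing_sigmas=(2.0, 1.0, 0.0),
                   learning_rate: float = 1.0,
                   iterations: int = 300) -> RigidTransform:
    """Estimate the rigid transform mapping fixed-world to moving-world.

    Intensity-based: normalized cross-correlation (default) or mean
    squares, optimized by regular-step gradient descent over a
    multi-resolution pyramid with dense (non-stochastic) sampling, so the
    result is deterministic for a given configuration.  The returned
    transform is directly usable by :func:`apply_rigid` to bring the moving
    image onto the fixed grid.
    """
    import SimpleITK as sitk

    f, m = _to_sitk(fixed), _to_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    if metric == "ncc":
        reg.SetMetricAsCorrelation()
    elif metric in ("mse", "mean_squares"):
        reg.SetMetricAsMeanSquares()
    else:
        raise ValueError(f"unknown metric {metric!r}")
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=learning_rate, minStep=1e-5,
        numberOfIterations=iterations, relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-8)
    reg.SetOptimizerScalesFromPhysicalShift()
    init = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY)
    reg.SetInitialTransform(init, inPlace=False)
    reg.SetShrinkFactorsPerLevel(list(shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    try:
        result = reg.Execute(f, m)
    except RuntimeError as exc:
        raise RegistrationError(f"rigid estimation failed: {exc}") from exc
    metric_value = reg.GetMetricValue()
    if not np.isfinite(metric_value):
        raise RegistrationError("similarity metric is non-finite (empty overlap?)")

    t = sitk.Euler3DTransform(result if not isinstance(result, sitk.CompositeTransform)
                              else result.GetNthTransform(0))
    R = np.asarray(t.GetMatrix(), dtype=float).reshape(3, 3)
    center = np.asarray(t.GetCenter(), dtype=float)
    translation = np.asarray(t.GetTranslation(), dtype=float)
    return RigidTransform(R, translation, center)
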