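"""Synthetic ADC/T1 phantom cases and cohorts.

The analysis needs paired-timepoint brain volumes with known ground truth:
a low-ADC tumor core, a high-ADC vasogenic edema shell, an infiltrated
edema sub-region that will later host recurrence, and a known rigid
misalignment between the pre- and post-recurrence scans.  Real cohorts of
this kind are not publicly depositable, so this module generates them.

Geometry is deliberately simple — spherical tumor, spherical-shell edema,
an angular wedge of infiltration — so that every truth mask is analytic.
Intensities are drawn from per-tissue normal components.  The sub-region
contrast that carries the max/mean signal is realized as spatially
clustered high-ADC foci (think microcystic, free-water pockets) admixed
into one of the two edema sub-regions:

* ``effect_direction="rec_lower_ratio"`` (default): foci go into the
  *non-infiltrated* shell, so the infiltrated (recurrence-prone) region
  has the **lower** max/mean ratio — matching a decision rule that calls
  recurrence where the ratio falls *below* a cutoff.
* ``effect_direction="rec_higher_ratio"``: foci go into the infiltration
  wedge instead.

Identical ``(spec, seed)`` pairs produce bit-identical phantoms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import GridGeometry, MaskVolume, VolumeImage, write_mask, write_volume
from .registration import RigidTransform, apply_rigid, apply_rigid_mask

EFFECT_DIRECTIONS = ("rec_lower_ratio", "rec_higher_ratio")

# T1 component means/sds (arbitrary units): enhancing tumor bright, edema
# dark, no contrast between edema sub-regions (mirrors the finding that T1
# intensities do not separate them).
_T1_COMPONENTS = {"background": (300.0, 30.0), "tumor": (600.0, 60.0),
                  "edema": (200.0, 20.0)}


class PhantomGeometryError(ValueError):
    """Raised when the requested geometry does not fit inside the grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    ADC means/sds are in 1e-6 mm^2/s.  ``infil_outlier_fraction`` is the
    target areal fraction of the focus admixture inside its sub-region and
    ``infil_outlier_scale`` the multiplicative contrast of focus voxels;
    ``focus_radius_mm`` sets the focus size.  ``misalignment`` is the rigid
    transform mapping pre-world to post-world coordinates (``None`` means
    the default 3 degrees about z plus 2 mm along x, about the grid
    centre).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 44)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    adc_background_mean: float = 750.0
    adc_background_sd: float = 50.0
    adc_tumor_mean: float = 600.0
    adc_tumor_sd: float = 80.0
    adc_edema_mean: float = 1500.0
    adc_edema_sd: float = 150.0
    adc_infil_mean: float = 1250.0
    adc_infil_sd: float = 200.0
    infil_outlier_fraction: float = 0.25
    infil_outlier_scale: float = 5.5
    focus_radius_mm: float = 0.45
    effect_direction: str = "rec_lower_ratio"
    tumor_radius_mm: float = 10.0
    edema_thickness_mm: float = 8.0
    infil_angular_fraction: float = 0.4
    wedge_angle_deg: float = 0.0
    wedge_irregularity_deg: float = 24.0
    misalignment: RigidTransform | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("adc_background_mean", "adc_tumor_mean",
                     "adc_edema_mean", "adc_infil_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("adc_background_sd", "adc_tumor_sd",
                     "adc_edema_sd", "adc_infil_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.infil_angular_fraction <= 1.0:
            raise ValueError("infil_angular_fraction must be in [0, 1]")
        if not 0.0 <= self.infil_outlier_fraction < 1.0:
            raise ValueError("infil_outlier_fraction must be in [0, 1)")
        if self.infil_outlier_scale <= 0:
            raise ValueError("infil_outlier_scale must be > 0")
        if self.effect_direction not in EFFECT_DIRECTIONS:
            raise ValueError(f"effect_direction must be one of {EFFECT_DIRECTIONS}")

    @property
    def grid(self) -> GridGeometry:
        return GridGeometry(tuple(self.grid_shape), tuple(self.spacing))

    def misalignment_transform(self) -> RigidTransform:
        if self.misalignment is not None:
            return self.misalignment
        return RigidTransform.from_euler(
            (0.0, 0.0, 3.0), (2.0, 0.0, 0.0), center=self.grid.center_world())


@dataclass
class PhantomCase:
    """One generated case: pre-timepoint volumes/masks plus misaligned
    post-timepoint data and the ground-truth infiltration mask."""

    adc_pre: VolumeImage
    t1_pre: VolumeImage
    adc_post: VolumeImage
    tumor_pre: MaskVolume
    edema_pre: MaskVolume
    tumor_rec_native: MaskVolume     # on the (misaligned) post grid
    truth_infiltration: MaskVolume   # ground-truth subedema-rec, pre grid
    spec: PhantomSpec
    case_id: str = "case"


def _focus_mask(rng: np.random.Generator, region: np.ndarray,
                fraction: float, radius_mm: float,
                spacing) -> np.ndarray:
    """Focus admixture: quasi-regularly spaced tubular fluid tracks.

    Foci are modelled as axially oriented columns (think dilated
    perivascular spaces threading the edema) of in-plane radius
    ``radius_mm``, centred on a jittered square lattice whose pitch is
    chosen so the in-plane covered fraction of the region matches
    ``fraction``.  The quasi-regular spacing means any few-voxel
    neighbourhood of the host sub-region sees roughly the same focus
    density — the texture the tile statistic keys on.
    """
    if fraction <= 0 or not region.any():
        return np.zeros_like(region, dtype=bool)
    n0, n1 = region.shape[0], region.shape[1]
    # rasterized in-plane footprint of one focus, centred on a voxel
    r0 = int(np.floor(radius_mm / spacing[0]))
    r1 = int(np.floor(radius_mm / spacing[1]))
    di, dj = np.mgrid[-r0:r0 + 1, -r1:r1 + 1]
    foot = (di * spacing[0]) ** 2 + (dj * spacing[1]) ** 2 <= radius_mm ** 2
    foot_idx = np.argwhere(foot) - (r0, r1)
    foot_area = foot_idx.shape[0] * spacing[0] * spacing[1]
    pitch_mm = float(np.sqrt(foot_area / fraction))
    # random global phase, then an exactly periodic voxel-snapped lattice:
    # uniform spacing keeps the focus texture homogeneous at tile scale
    offset = rng.uniform(0.0, pitch_mm, size=2)
    cx = np.arange(offset[0] - pitch_mm, n0 * spacing[0] + pitch_mm, pitch_mm)
    cy = np.arange(offset[1] - pitch_mm, n1 * spacing[1] + pitch_mm, pitch_mm)
    GX, GY = np.meshgrid(cx, cy, indexing="ij")
    gi = np.rint(GX / spacing[0]).astype(int).ravel()
    gj = np.rint(GY / spacing[1]).astype(int).ravel()
    inplane = np.zeros((n0, n1), dtype=bool)
    for oi, oj in foot_idx:
        ii, jj = gi + oi, gj + oj
        ok = (ii >= 0) & (ii < n0) & (jj >= 0) & (jj < n1)
        inplane[ii[ok], jj[ok]] = True
    return inplane[:, :, None] & region


def generate_phantom(spec: PhantomSpec, case_id: str = "case") -> PhantomCase:
    """Build one phantom case from its spec (deterministic in the seed)."""
    grid = spec.grid
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    rng = np.random.default_rng(spec.seed)

    half_extent = (np.asarray(shape) - 1) * spacing / 2.0
    brain_radius = float(min(half_extent[:2])) - 2.0 * float(max(spacing[:2]))
    outer = spec.tumor_radius_mm + spec.edema_thickness_mm
    if outer >= brain_radius:
        raise PhantomGeometryError(
            f"tumor radius + edema thickness = {outer:.1f} mm does not fit "
            f"inside the brain radius {brain_radius:.1f} mm for grid "
            f"{shape} at spacing {tuple(spacing)}; shrink the lesion or "
            f"enlarge the grid")

    center = grid.center_world()
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    world = grid.index_to_world(
        np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)).reshape(*shape, 3)
    rel = world - center
    dist = np.sqrt((rel ** 2).sum(axis=-1))
    # flatten the z-extent of the brain ellipsoid to the grid
    brain = ((rel[..., 0] / brain_radius) ** 2 + (rel[..., 1] / brain_radius) ** 2
             + (rel[..., 2] / half_extent[2]) ** 2) <= 1.0

    tumor = dist <= spec.tumor_radius_mm
    edema = (dist > spec.tumor_radius_mm) & (dist <= outer)

    if spec.infil_angular_fraction > 0:
        theta = np.degrees(np.arctan2(rel[..., 1], rel[..., 0]))  # [-180, 180)
        # irregular infiltration front: both angular edges of the wedge
        # wiggle with radius (infiltration margins are not straight)
        phase = rng.uniform(0.0, 2 * np.pi, size=2)
        radial = 2 * np.pi * (dist - spec.tumor_radius_mm) / 4.0
        lo = spec.wedge_irregularity_deg * np.sin(radial + phase[0])
        hi = spec.wedge_irregularity_deg * np.sin(radial + phase[1])
        width = 360.0 * spec.infil_angular_fraction
        rel_angle = np.mod(theta - spec.wedge_angle_deg - lo, 360.0)
        wedge = rel_angle < np.maximum(width + hi - lo, 0.0)
        infil = edema & wedge
    else:
        infil = np.zeros(shape, dtype=bool)
    edema_only = edema & ~infil
    background = brain & ~tumor & ~edema

    # Intensity draws in a fixed region order keeps determinism explicit.
    adc = np.zeros(shape, dtype=float)
    adc[background] = rng.normal(spec.adc_background_mean,
                                 spec.adc_background_sd, int(background.sum()))
    adc[tumor] = rng.normal(spec.adc_tumor_mean, spec.adc_tumor_sd,
                            int(tumor.sum()))
    adc[edema_only] = rng.normal(spec.adc_edema_mean, spec.adc_edema_sd,
                                 int(edema_only.sum()))
    adc[infil] = rng.normal(spec.adc_infil_mean, spec.adc_infil_sd,
                            int(infil.sum()))

    focus_region = edema_only if spec.effect_direction == "rec_lower_ratio" else infil
    foci = _focus_mask(rng, focus_region, spec.infil_outlier_fraction,
                       spec.focus_radius_mm, spacing)
    adc[foci] *= spec.infil_outlier_scale

    t1 = np.zeros(shape, dtype=float)
    for region, key in ((background, "background"), (tumor, "tumor"),
                        (edema, "edema")):
        mu, sd = _T1_COMPONENTS[key]
        t1[region] = rng.normal(mu, sd, int(region.sum()))

    # Post-recurrence anatomy on the pre grid: recurrent tumor fills the
    # previous core plus the infiltrated wedge with tumor-like ADC.
    tumor_rec_pre = tumor | infil
    adc_post_pre = adc.copy()
    adc_post_pre[tumor_rec_pre] = rng.normal(
        spec.adc_tumor_mean, spec.adc_tumor_sd, int(tumor_rec_pre.sum()))

    T = spec.misalignment_transform()
    Tinv = T.invert()
    adc_post = apply_rigid(VolumeImage(adc_post_pre, grid, units="ADC 1e-6 mm^2/s"),
                           Tinv, grid)
    tumor_rec_native = apply_rigid_mask(MaskVolume(tumor_rec_pre, grid), Tinv, grid)

    return PhantomCase(
        adc_pre=VolumeImage(adc, grid, units="ADC 1e-6 mm^2/s"),
        t1_pre=VolumeImage(t1, grid, units="T1 a.u."),
        adc_post=adc_post,
        tumor_pre=MaskVolume(tumor, grid),
        edema_pre=MaskVolume(edema, grid),
        tumor_rec_native=tumor_rec_native,
        truth_infiltration=MaskVolume(infil, grid),
        spec=spec,
        case_id=case_id,
    )


def generate_cohort(n_cases: int, spec: PhantomSpec, seed: int,
                    radius_jitter: float = 0.15,
                    thickness_jitter: float = 0.15,
                    fraction_jitter: float = 0.25) -> list[PhantomCase]:
    """Generate a cohort with per-case geometric jitter.

    Per-case seeds derive deterministically from ``seed``.  Tumor radius
    and edema thickness are jittered by the given relative uniform ranges,
    the wedge orientation uniformly over the full circle and the wedge
    angular fraction by ``fraction_jitter`` (relative, clipped to [0, 1]).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    master = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        case_seed = int(master.integers(0, 2 ** 31 - 1))
        jit = np.random.default_rng(case_seed)
        r = spec.tumor_radius_mm * (1 + radius_jitter * jit.uniform(-1, 1))
        th = spec.edema_thickness_mm * (1 + thickness_jitter * jit.uniform(-1, 1))
        frac = float(np.clip(
            spec.infil_angular_fraction * (1 + fraction_jitter * jit.uniform(-1, 1)),
            0.0, 1.0))
        angle = jit.uniform(0.0, 360.0)
        case_spec = dataclasses.replace(
            spec, tumor_radius_mm=r, edema_thickness_mm=th,
            infil_angular_fraction=frac, wedge_angle_deg=angle, seed=case_seed)
        cases.append(generate_phantom(case_spec, case_id=f"case{i + 1:03d}"))
    return cases


# ---------------------------------------------------------------------------
# Tabular cohort simulator (feature level)


FEATURE_NAMES = ("meanADC", "stdmeanADC", "maxiADC", "miniADC", "medianADC",
                 "skewnessADC", "kurtosisADC", "ratio_maxi_mean")


def simulate_feature_cohort(n_cases: int, seed: int,
                            effect_size: float = 1.2,
                            effect_feature: str = "ratio_maxi_mean"):
    """Feature-level cohort with a planted standardized effect.

    Returns a table with one ``rec`` and one ``no_rec`` row per case.  All
    eight histogram features are independent unit normals except
    ``effect_feature``, whose mean differs by ``effect_size`` standard
    deviations between the two sub-volume classes (no_rec higher,
    mirroring the lower-ratio-in-recurrence default direction).  Used for
    selection-recovery experiments where image generation would only add
    noise around the same question.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cases):
        for label, is_rec in (("rec", 1), ("no_rec", 0)):
            feats = {f: rng.normal() for f in FEATURE_NAMES}
            if not is_rec:
                feats[effect_feature] += effect_size
            rows.append({"case_id": f"case{i + 1:03d}", "subvolume": label,
                         "label": is_rec, **feats})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization / export


def spec_to_json(spec: PhantomSpec, path=None) -> str:
    """Serialize a spec as JSON (the package's config dialect)."""
    d = dataclasses.asdict(spec)
    T = spec.misalignment
    d["misalignment"] = None if T is None else {
        "matrix4": T.matrix4().tolist(), "center": T.center.tolist()}
    text = json.dumps(d, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def spec_from_json(source) -> PhantomSpec:
    if hasattr(source, "read"):
        d = json.load(source)
    else:
        try:
            d = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                d = json.load(fh)
    if d.get("misalignment") is not None:
        m = d["misalignment"]
        d["misalignment"] = RigidTransform.from_matrix4(
            np.asarray(m["matrix4"]), center=m["center"])
    for key in ("grid_shape", "spacing"):
        d[key] = tuple(d[key])
    return PhantomSpec(**d)


def export_case(case: PhantomCase, directory) -> dict:
    """Write a case's volumes and labelmaps as NIfTI files; returns paths."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in (("adc_pre", case.adc_pre), ("t1_pre", case.t1_pre),
                      ("adc_post", case.adc_post)):
        p = directory / f"{case.case_id}_{name}.nii.gz"
        write_volume(vol, p)
        paths[name] = p
    for name, mask in (("tumor_pre", case.tumor_pre),
                       ("edema_pre", case.edema_pre),
                       ("tumor_rec_native", case.tumor_rec_native),
                       ("truth_infiltration", case.truth_infiltration)):
        p = directory / f"{case.case_id}_{name}.nii.gz"
        write_mask(mask, p)
        paths[name] = p
    spec_to_json(case.spec, directory / f"{case.case_id}_spec.json")
    paths["spec"] = directory / f"{case.case_id}_spec.json"
    return paths
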