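"""Tile-based prediction of the recurrence-prone edema sub-volume.

On the axial slice with the largest tumor area (among slices that also
carry edema), the edema region is partitioned into square tiles of 2,
2.5 or 3 voxels per side.  Each tile is scored by

    tile value = (max ADC within the tile's edema voxels)
                 / (mean ADC over the whole edema ROI on that slice),

and tiles whose value falls *below* the threshold (default 2.408) are
predicted as recurrence-prone (direction ``below_positive``; the
opposite direction is configurable).  The whole-ROI mean is used as the
denominator because a 4-voxel tile's internal max/mean is bounded near
1 and a threshold like 2.408 could never fire against it.

Fractional tile sizes are realized exactly on a 2x upsampled grid
(2.5 voxels -> 5 fine cells); all tiling therefore happens on the fine
grid for every size.  The fine grid replicates each native voxel into
its 2x2 fine cells (nearest resampling): the tile statistic is a *max*,
and an interpolating resampler would attenuate isolated maxima by up to
~44%, quietly changing the statistic being thresholded.  Tiles are
anchored at the corner of the edema bounding box, and a tile is
evaluated only when at least half of its nominal area lies inside the
edema ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import GeometryError, GridGeometry, MaskVolume, VolumeImage

FINE = 2  # upsampling factor realizing fractional tile sizes
STANDARD_TILE_SIZES = (2.0, 2.5, 3.0)
DEFAULT_THRESHOLD = 2.408


def select_slice(tumor_pre: MaskVolume, edema_pre: MaskVolume) -> int:
    """Axial slice maximizing tumor area among slices with nonzero edema.

    Ties break toward the lowest index.  Raises ``ValueError`` when no
    slice carries both structures.
    """
    if not tumor_pre.grid.same_grid(edema_pre.grid):
        raise GeometryError("tumor and edema masks are on different grids")
    tumor_area = tumor_pre.data.sum(axis=(0, 1))
    edema_area = edema_pre.data.sum(axis=(0, 1))
    ok = (tumor_area > 0) & (edema_area > 0)
    if not ok.any():
        raise ValueError("no axial slice contains both tumor and edema")
    masked = np.where(ok, tumor_area, -1)
    return int(np.argmax(masked))  # argmax takes the first (lowest) maximum


def _upsample(slice2d: np.ndarray, order: int) -> np.ndarray:
    """2x upsample; fine cell (f) centres native coordinate f/2 - 1/4."""
    n0, n1 = slice2d.shape
    f0 = np.arange(FINE * n0) / FINE - 0.25
    f1 = np.arange(FINE * n1) / FINE - 0.25
    coords = np.meshgrid(f0, f1, indexing="ij")
    return ndimage.map_coordinates(np.asarray(slice2d, dtype=float),
                                   coords, order=order, mode="nearest")


@dataclass
class TileHeatmap:
    """Per-tile ratio values and thresholded prediction on one slice."""

    slice_index: int
    tile_size: float                  # voxels per side (2, 2.5, 3, ...)
    threshold: float
    direction: str                    # "below_positive" | "above_positive"
    tile_origin: tuple[int, int]      # fine-grid anchor (edema bbox corner)
    values: np.ndarray                # (n_tiles0, n_tiles1); NaN = not evaluated
    predicted_mask: np.ndarray        # fine-grid 2-D bool over the slice
    roi_mean: float
    grid: GridGeometry                # native 3-D grid of the source volume

    @property
    def n_evaluated(self) -> int:
        return int(np.isfinite(self.values).sum())

    def predicted_mask_native(self) -> np.ndarray:
        """Downsample the fine prediction to native voxels (majority)."""
        n0, n1 = (s // FINE for s in self.predicted_mask.shape)
        blocks = self.predicted_mask[:n0 * FINE, :n1 * FINE].reshape(
            n0, FINE, n1, FINE)
        return blocks.sum(axis=(1, 3)) >= (FINE * FINE) // 2 + 1


def tile_ratio_map(adc: VolumeImage, edema_pre: MaskVolume, slice_index: int,
                   tile_size: float = 2.0,
                   threshold: float = DEFAULT_THRESHOLD,
                   direction: str = "below_positive") -> TileHeatmap:
    """Score edema tiles on one slice and threshold them.

    See the module docstring for the tile statistic and conventions.
    """
    import warnings

    if direction not in ("below_positive", "above_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    if not edema_pre.grid.same_grid(adc.grid):
        raise GeometryError("ADC volume and edema mask are on different grids")
    if float(tile_size) not in STANDARD_TILE_SIZES:
        warnings.warn(f"non-standard tile size {tile_size}; standard sizes "
                      f"are {STANDARD_TILE_SIZES}", stacklevel=2)
    span = int(round(tile_size * FINE))
    if span < 1:
        raise ValueError("tile size too small")

    adc2d = np.asarray(adc.data, dtype=float)[:, :, slice_index]
    edema2d = edema_pre.data[:, :, slice_index]
    if not edema2d.any():
        raise ValueError(f"edema is empty on slice {slice_index}")
    roi_mean = float(adc2d[edema2d].mean())
    if roi_mean <= 0:
        raise ValueError("ROI mean ADC must be positive")

    fine_adc = _upsample(adc2d, order=0)   # replication: preserves maxima
    fine_edema = _upsample(edema2d.astype(float), order=0) > 0.5

    rows = np.flatnonzero(fine_edema.any(axis=1))
    cols = np.flatnonzero(fine_edema.any(axis=0))
    r0, c0 = int(rows[0]), int(cols[0])
    n_r = int(np.ceil((rows[-1] + 1 - r0) / span))
    n_c = int(np.ceil((cols[-1] + 1 - c0) / span))

    values = np.full((n_r, n_c), np.nan)
    predicted = np.zeros_like(fine_edema, dtype=bool)
    half_area = 0.5 * span * span
    for a in range(n_r):
        for b in range(n_c):
            rs, cs = r0 + a * span, c0 + b * span
            tile_e = fine_edema[rs:rs + span, cs:cs + span]
            if tile_e.sum() < half_area:
                continue
            tile_adc = fine_adc[rs:rs + span, cs:cs + span]
            v = float(tile_adc[tile_e].max()) / roi_mean
            values[a, b] = v
            hit = v < threshold if direction == "below_positive" else v > threshold
            if hit:
                predicted[rs:rs + span, cs:cs + span] = True
    if not np.isfinite(values).any():
        raise ValueError("no evaluable tile: edema too small for this tile size")

    return TileHeatmap(
        slice_index=slice_index, tile_size=float(tile_size),
        threshold=float(threshold), direction=direction,
        tile_origin=(r0, c0), values=values, predicted_mask=predicted,
        roi_mean=roi_mean, grid=adc.grid)


def evaluate_prediction(heatmap: TileHeatmap, truth_rec: MaskVolume,
                        edema_pre: MaskVolume) -> tuple[float, float]:
    """Voxel accuracy and Dice of the prediction, restricted to edema.

    Both scores are computed on the fine grid of the heatmap's slice
    (identical to native-voxel scoring for integer tile sizes).
    Positives are recurrence voxels.
    """
    if not truth_rec.grid.same_grid(heatmap.grid) \
            or not edema_pre.grid.same_grid(heatmap.grid):
        raise GeometryError("masks are not on the heatmap's grid")
    k = heatmap.slice_index
    fine_edema = _upsample(edema_pre.data[:, :, k].astype(float), order=0) > 0.5
    fine_truth = _upsample(truth_rec.data[:, :, k].astype(float), order=0) > 0.5
    pred = heatmap.predicted_mask & fine_edema
    truth = fine_truth & fine_edema
    total = int(fine_edema.sum())
    if total == 0:
        raise ValueError("edema empty on the heatmap slice")
    tp = int((pred & truth).sum())
    tn = int((~pred & ~truth & fine_edema).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth & fine_edema).sum())
    accuracy = (tp + tn) / total
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    return float(accuracy), float(dice)


def render_heatmap(heatmap: TileHeatmap, background: VolumeImage, path,
                   cmap: str = "jet", alpha: float = 0.45,
                   dpi: int = 150) -> None:
    """Render tile values alpha-blended over the grayscale slice.

    Deterministic pixels for a fixed colormap and matplotlib version;
    PNG output is byte-reproducible (JPG may differ by encoder).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not background.grid.same_grid(heatmap.grid):
        raise GeometryError("background volume is not on the heatmap's grid")
    bg = _upsample(np.asarray(background.data, dtype=float)
                   [:, :, heatmap.slice_index], order=1)
    # expand per-tile values onto the fine grid for display
    span = int(round(heatmap.tile_size * FINE))
    r0, c0 = heatmap.tile_origin
    overlay = np.full(bg.shape, np.nan)
    n_r, n_c = heatmap.values.shape
    for a in range(n_r):
        for b in range(n_c):
            v = heatmap.values[a, b]
            if np.isfinite(v):
                overlay[r0 + a * span:r0 + (a + 1) * span,
                        c0 + b * span:c0 + (b + 1) * span] = v

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(bg.T, cmap="gray", origin="lower", interpolation="nearest")
    im = ax.imshow(np.ma.masked_invalid(overlay).T, cmap=cmap,
                   origin="lower", alpha=alpha, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="tile max ADC / ROI mean ADC")
    ax.contour(heatmap.predicted_mask.T.astype(float), levels=[0.5],
               colors="white", linewidths=0.8)
    ax.set_title(f"slice {heatmap.slice_index}, "
                 f"{heatmap.tile_size}x{heatmap.tile_size} tiles, "
                 f"threshold {heatmap.threshold}")
    ax.set_axis_off()
    fig.savefig(str(path), dpi=dpi, metadata={"Software": None}
                if str(path).lower().endswith(".png") else None)
    plt.close(fig)


def write_prediction_mask(heatmap: TileHeatmap, path) -> None:
    """Export the native-resolution predicted mask as a one-slice NIfTI."""
    import nibabel as nib

    native = heatmap.predicted_mask_native().astype(np.uint8)
    data = native[:, :, None]
    grid = heatmap.grid
    origin = np.asarray(grid.origin) + grid.direction_matrix @ (
        np.array([0.0, 0.0, heatmap.slice_index * grid.spacing[2]]))
    g = GridGeometry(shape=(data.shape[0], data.shape[1], 1),
                     spacing=grid.spacing, origin=tuple(origin),
                     direction=grid.direction)
    nib.save(nib.Nifti1Image(data, g.affine), str(path))
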