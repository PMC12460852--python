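"""Tile heatmap: slice selection, tile statistics, scoring, rendering."""

import numpy as np
import pytest

from edemarec.heatmap import (FINE, TileHeatmap, evaluate_prediction,
                              render_heatmap, select_slice, tile_ratio_map,
                              write_prediction_mask, _upsample)
from edemarec.imaging import GridGeometry, MaskVolume, VolumeImage


def _vol(data, spacing=(1, 1, 1)):
    data = np.asarray(data, dtype=float)
    return VolumeImage(data, GridGeometry(data.shape, spacing))


def _mask(data, spacing=(1, 1, 1)):
    data = np.asarray(data, dtype=bool)
    return MaskVolume(data, GridGeometry(data.shape, spacing))


def _flat_scene(nx=20, ny=20, nz=3, edema_lo=2, edema_hi=18, value=1000.0):
    adc = np.full((nx, ny, nz), value)
    edema = np.zeros((nx, ny, nz), dtype=bool)
    edema[edema_lo:edema_hi, edema_lo:edema_hi, 1] = True
    return _vol(adc), _mask(edema)


# ---------------------------------------------------------------------------
# select_slice


def test_select_slice_peak_tumor_with_edema():
    tumor = np.zeros((8, 8, 5), dtype=bool)
    edema = np.zeros((8, 8, 5), dtype=bool)
    tumor[2:6, 2:6, 2] = True            # area 16 at slice 2
    tumor[3:5, 3:5, 3] = True            # area 4 at slice 3
    edema[0, 0, 2] = edema[0, 0, 3] = True
    assert select_slice(_mask(tumor), _mask(edema)) == 2


def test_select_slice_skips_edemaless_peak():
    tumor = np.zeros((8, 8, 5), dtype=bool)
    edema = np.zeros((8, 8, 5), dtype=bool)
    tumor[1:7, 1:7, 1] = True            # biggest, but no edema there
    tumor[3:5, 3:5, 3] = True
    edema[0, 0, 3] = True
    assert select_slice(_mask(tumor), _mask(edema)) == 3


def test_select_slice_tie_breaks_low():
    tumor = np.zeros((8, 8, 5), dtype=bool)
    edema = np.ones((8, 8, 5), dtype=bool)
    tumor[2:4, 2:4, 1] = True
    tumor[2:4, 2:4, 3] = True
    assert select_slice(_mask(tumor), _mask(edema)) == 1


def test_select_slice_requires_both_structures():
    tumor = np.zeros((4, 4, 2), dtype=bool)
    edema = np.zeros((4, 4, 2), dtype=bool)
    tumor[1, 1, 0] = True
    edema[1, 1, 1] = True
    with pytest.raises(ValueError):
        select_slice(_mask(tumor), _mask(edema))


# ---------------------------------------------------------------------------
# tile_ratio_map


def test_constant_field_gives_unit_tiles_all_positive():
    adc, edema = _flat_scene()
    hm = tile_ratio_map(adc, edema, 1, tile_size=2, threshold=2.408)
    vals = hm.values[np.isfinite(hm.values)]
    assert np.allclose(vals, 1.0)
    # every evaluated tile is below threshold -> positive
    assert hm.predicted_mask.any()
    fine_edema = _upsample(edema.data[:, :, 1].astype(float), 0) > 0.5
    assert not np.any(hm.predicted_mask & ~_dilate_to_tiles(hm, fine_edema))


def _dilate_to_tiles(hm, fine_edema):
    """Cells belonging to any evaluated tile."""
    span = int(round(hm.tile_size * FINE))
    out = np.zeros_like(fine_edema)
    r0, c0 = hm.tile_origin
    for a in range(hm.values.shape[0]):
        for b in range(hm.values.shape[1]):
            if np.isfinite(hm.values[a, b]):
                out[r0 + a * span:r0 + (a + 1) * span,
                    c0 + b * span:c0 + (b + 1) * span] = True
    return out


def test_single_hot_voxel_flips_its_tile_negative():
    adc, edema = _flat_scene(value=1000.0)
    data = adc.data.copy()
    data[4, 4, 1] = 3000.0 * (1.0 + 1e-9)    # approximately 3x the ROI mean
    adc = _vol(data)
    roi_mean = data[:, :, 1][edema.data[:, :, 1]].mean()
    hm = tile_ratio_map(adc, edema, 1, tile_size=2, threshold=2.408)
    r0, c0 = hm.tile_origin
    a, b = (4 * FINE - r0) // (2 * FINE), (4 * FINE - c0) // (2 * FINE)
    assert hm.values[a, b] == pytest.approx(3000.0 / roi_mean, rel=1e-6)
    assert hm.values[a, b] > 2.408
    # that tile is predicted negative; its cells are outside the mask
    span = 2 * FINE
    assert not hm.predicted_mask[r0 + a * span: r0 + (a + 1) * span,
                                 c0 + b * span: c0 + (b + 1) * span].any()


@pytest.mark.parametrize("tile_size", [2.0, 2.5, 3.0])
def test_tile_values_match_loop_oracle(default_case, tile_size):
    """Brute-force re-tiling of a phantom slice reproduces every value."""
    k = select_slice(default_case.tumor_pre, default_case.edema_pre)
    hm = tile_ratio_map(default_case.adc_pre, default_case.edema_pre, k,
                        tile_size=tile_size)
    adc2 = np.repeat(np.repeat(default_case.adc_pre.data[:, :, k], 2, 0), 2, 1)
    ede2 = np.repeat(np.repeat(default_case.edema_pre.data[:, :, k], 2, 0), 2, 1)
    roi_mean = default_case.adc_pre.data[:, :, k][
        default_case.edema_pre.data[:, :, k]].mean()
    span = int(round(tile_size * FINE))
    r0, c0 = hm.tile_origin
    n_r, n_c = hm.values.shape
    for a in range(n_r):
        for b in range(n_c):
            rs, cs = r0 + a * span, c0 + b * span
            te = ede2[rs:rs + span, cs:cs + span]
            expected = np.nan
            if te.sum() >= 0.5 * span * span:
                expected = adc2[rs:rs + span, cs:cs + span][te].max() / roi_mean
            got = hm.values[a, b]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, rel=1e-12)


def test_tiling_is_a_partition(default_case):
    """No fine cell belongs to two evaluated tiles."""
    k = select_slice(default_case.tumor_pre, default_case.edema_pre)
    hm = tile_ratio_map(default_case.adc_pre, default_case.edema_pre, k,
                        tile_size=2.5)
    span = int(round(2.5 * FINE))
    counts = np.zeros(hm.predicted_mask.shape, dtype=int)
    r0, c0 = hm.tile_origin
    for a in range(hm.values.shape[0]):
        for b in range(hm.values.shape[1]):
            if np.isfinite(hm.values[a, b]):
                counts[r0 + a * span:r0 + (a + 1) * span,
                       c0 + b * span:c0 + (b + 1) * span] += 1
    assert counts.max() <= 1


def test_threshold_monotonicity(default_case):
    """Raising the threshold never shrinks the predicted-positive set."""
    k = select_slice(default_case.tumor_pre, default_case.edema_pre)
    prev = None
    for thr in (1.5, 2.0, 2.408, 3.5, 6.0):
        hm = tile_ratio_map(default_case.adc_pre, default_case.edema_pre, k,
                            tile_size=2, threshold=thr)
        if prev is not None:
            assert np.all(prev <= hm.predicted_mask)
        prev = hm.predicted_mask


def test_nonstandard_tile_size_warns():
    adc, edema = _flat_scene()
    with pytest.warns(UserWarning, match="non-standard"):
        tile_ratio_map(adc, edema, 1, tile_size=4.0)


def test_empty_edema_slice_rejected():
    adc, edema = _flat_scene()
    with pytest.raises(ValueError, match="empty"):
        tile_ratio_map(adc, edema, 0, tile_size=2)


# ---------------------------------------------------------------------------
# evaluate_prediction


def _square_truth(edema, lo, hi):
    truth = np.zeros_like(edema.data)
    truth[lo:hi, lo:hi, 1] = True
    truth &= edema.data
    return MaskVolume(truth, edema.grid)


def test_perfect_prediction_scores_one():
    adc, edema = _flat_scene()
    truth = _square_truth(edema, 2, 18)     # truth == edema
    hm = tile_ratio_map(adc, edema, 1, tile_size=2, threshold=2.408)
    acc, dc = evaluate_prediction(hm, truth, edema)
    assert acc == pytest.approx(1.0)
    assert dc == pytest.approx(1.0)


def test_complement_prediction_scores_zero():
    adc, edema = _flat_scene()
    truth = MaskVolume(np.zeros_like(edema.data), edema.grid)
    hm = tile_ratio_map(adc, edema, 1, tile_size=2, threshold=2.408)
    acc, dc = evaluate_prediction(hm, truth, edema)   # all-positive vs empty
    assert acc == pytest.approx(0.0)
    assert dc == pytest.approx(0.0)


def test_all_positive_prediction_closed_form():
    adc, edema = _flat_scene(edema_lo=2, edema_hi=18)
    truth = _square_truth(edema, 2, 11)
    hm = tile_ratio_map(adc, edema, 1, tile_size=2, threshold=2.408)
    frac = truth.data.sum() / edema.data.sum()
    acc, dc = evaluate_prediction(hm, truth, edema)
    assert acc == pytest.approx(frac, abs=1e-12)
    assert dc == pytest.approx(2 * frac / (1 + frac), abs=1e-12)


# ---------------------------------------------------------------------------
# rendering / export


def test_render_png_is_deterministic(tmp_path, default_case):
    k = select_slice(default_case.tumor_pre, default_case.edema_pre)
    hm = tile_ratio_map(default_case.adc_pre, default_case.edema_pre, k)
    p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
    render_heatmap(hm, default_case.adc_pre, p1)
    render_heatmap(hm, default_case.adc_pre, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert p1.stat().st_size > 1000


def test_prediction_mask_export(tmp_path, default_case):
    import nibabel as nib

    k = select_slice(default_case.tumor_pre, default_case.edema_pre)
    hm = tile_ratio_map(default_case.adc_pre, default_case.edema_pre, k)
    path = tmp_path / "pred.nii.gz"
    write_prediction_mask(hm, path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    assert data.shape[2] == 1
    assert set(np.unique(data)) <= {0.0, 1.0}
    assert data.sum() > 0
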