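"""First-order ADC histogram features of a region of interest.

Eight per-ROI statistics: meanADC, stdmeanADC (sample sd, N-1), maxiADC,
miniADC, medianADC, skewnessADC (g1 = m3 / m2^{3/2}), kurtosisADC
(m4 / m2^2, *non-excess* by default — the common radiomics convention;
an ``excess`` switch subtracts 3) and the ratio maxiADC / meanADC, the
discriminative statistic of the pipeline.

Skewness and kurtosis are reported as missing (NaN) when undefined
(fewer than 3 voxels or zero variance) rather than coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import MaskVolume, VolumeImage

FEATURE_COLUMNS = ("meanADC", "stdmeanADC", "maxiADC", "miniADC",
                   "medianADC", "skewnessADC", "kurtosisADC",
                   "ratio_maxi_mean")


@dataclass(frozen=True)
class HistogramFeatures:
    meanADC: float
    stdmeanADC: float
    maxiADC: float
    miniADC: float
    medianADC: float
    skewnessADC: float      # NaN when undefined
    kurtosisADC: float      # NaN when undefined
    ratio_maxi_mean: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_COLUMNS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FEATURE_COLUMNS])


def extract_features(volume: VolumeImage, mask: MaskVolume,
                     kurtosis: str = "raw") -> HistogramFeatures:
    """Compute the eight histogram features of ``volume`` inside ``mask``.

    ``kurtosis`` is ``"raw"`` (m4/m2^2) or ``"excess"`` (subtract 3).
    Raises ``ValueError`` for an empty mask, off-grid mask, non-finite
    masked intensities, or a zero mean (the ratio is then undefined).
    """
    if kurtosis not in ("raw", "excess"):
        raise ValueError(f"kurtosis must be 'raw' or 'excess', got {kurtosis!r}")
    if not mask.grid.same_grid(volume.grid):
        raise ValueError("mask and volume are on different grids")
    x = np.asarray(volume.data, dtype=float)[mask.data]
    n = x.size
    if n == 0:
        raise ValueError("empty mask: no voxels to summarize")
    if not np.all(np.isfinite(x)):
        raise ValueError("masked intensities contain non-finite values")

    mean = float(x.mean())
    if mean == 0.0:
        raise ValueError("ROI mean is zero; max/mean ratio undefined")
    std = float(x.std(ddof=1)) if n >= 2 else float("nan")
    xmax = float(x.max())
    xmin = float(x.min())
    median = float(np.median(x))

    if n >= 3:
        d = x - mean
        m2 = float(np.mean(d ** 2))
        if m2 > 0:
            skew = float(np.mean(d ** 3)) / m2 ** 1.5
            kurt = float(np.mean(d ** 4)) / m2 ** 2
            if kurtosis == "excess":
                kurt -= 3.0
        else:
            skew = kurt = float("nan")
    else:
        skew = kurt = float("nan")

    return HistogramFeatures(
        meanADC=mean, stdmeanADC=std, maxiADC=xmax, miniADC=xmin,
        medianADC=median, skewnessADC=skew, kurtosisADC=kurt,
        ratio_maxi_mean=xmax / mean)
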