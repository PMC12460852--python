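"""Single-case location prediction: where inside the edema will the
tumor recur?

Selects the slice with the largest tumor area, tiles the edema in 2x2
voxel units, scores each tile by (tile max ADC) / (slice ROI mean ADC),
thresholds at 2.408 (below -> recurrence-prone), and scores the
prediction against the phantom's planted infiltration.
"""

import tempfile
from pathlib import Path

from edemarec import (PhantomSpec, generate_phantom, run_case_prediction)

case = generate_phantom(PhantomSpec(seed=11))
out = Path(tempfile.mkdtemp())

for tile_size in (2.0, 2.5, 3.0):
    pred = run_case_prediction(
        case.adc_pre, case.edema_pre,
        tumor_pre=case.tumor_pre, truth_rec=case.truth_infiltration,
        tile_size=tile_size,
        raster_path=out / f"heatmap_{tile_size}.png" if tile_size == 2.0 else None)
    hm = pred.heatmap
    print(f"{tile_size:>3} x {tile_size} tiles: {hm.n_evaluated:3d} evaluated, "
          f"accuracy {pred.accuracy:.3f}, dice {pred.dice:.3f} "
          f"(slice {pred.slice_index}, threshold {pred.threshold})")
print(f"\nheatmap raster written to {out / 'heatmap_2.0.png'}")
# Accuracy and Dice are computed over edema voxels only; finer tiles
# resolve the irregular infiltration margin better, so 2x2 units score
# highest -- the ordering the predictor is designed around.
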