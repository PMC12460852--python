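# edemarec

Locating the recurrence-prone sub-volume of glioblastoma peritumoral
edema from ADC-map histogram features.

Glioblastoma almost always recurs, usually inside the T2-FLAIR
hyperintense edema that surrounded the original tumor — but not
uniformly: only part of that edema is infiltrated. `edemarec`
implements an image-analysis pipeline that asks *which part*, using the
apparent diffusion coefficient (ADC) map from diffusion-weighted MRI:

1. rigidly register the post-recurrence scan to the pre-recurrence
   grid and split the old edema into the part later overlapped by
   recurrent tumor (`subedema-rec`) and the remainder
   (`subedema-no-rec`);
2. extract eight first-order histogram statistics per sub-volume
   (mean, SD, max, min, median, skewness, kurtosis) plus the
   discriminative statistic of the pipeline, the **max/mean ADC
   ratio** `ratio = maxiADC / meanADC`;
3. screen the features with a cross-validated logistic LASSO, refine
   by forward stepwise logistic regression, and quantify separation by
   ROC analysis with a Youden-index cutpoint (SVM and random-forest
   baselines under the same seeded cross-validation);
4. turn the ROI-level rule into a **location predictor**: tile the
   edema on the slice with the largest tumor area in 2×2 (or 2.5×2.5,
   3×3) voxel units, score each tile by
   `tile max ADC / slice ROI mean ADC`, and mark tiles *below* a
   threshold (default 2.408) as recurrence-prone.

Because paired-timepoint clinical cohorts with contours cannot be
redistributed, the package ships a first-class synthetic-data module:
phantoms with a low-ADC tumor core, a high-ADC edema shell threaded by
fluid-track foci, an irregular infiltrated wedge with known ground
truth, and a planted rigid misalignment between timepoints. Every
stage of the pipeline is tested against that ground truth and against
brute-force oracles. `docs/methods.md` describes the model and the
phantom's assumptions in detail.

## Worked example

```python
from edemarec import (PhantomSpec, generate_phantom, run_case_prediction)

case = generate_phantom(PhantomSpec(seed=11))
pred = run_case_prediction(case.adc_pre, case.edema_pre,
                           tumor_pre=case.tumor_pre,
                           truth_rec=case.truth_infiltration, tile_size=2)
print(pred.slice_index, pred.heatmap.n_evaluated, pred.accuracy, pred.dice)
```

prints

```
21 176 0.9034090909090909 0.8815331010452961
```

meaning: on axial slice 21 (the slice with the largest tumor area that
also carries edema), 176 tiles of 2×2 voxels were evaluable inside the
edema; thresholding their max/mean-ADC values at 2.408 predicted the
infiltrated sub-region with 90.3% voxel accuracy and a Dice overlap of
0.88 against the phantom's planted ground truth. Running
`python examples/heatmap_prediction.py` reproduces these numbers and
adds the coarser tile sizes (2.5×2.5: accuracy 0.870; 3×3: 0.893 on
this case — over cohorts of phantoms the 2×2 unit scores best on
average, which is the ordering the predictor is designed around).

The other example scripts each exercise one capability end to end:

| script | what it shows |
| --- | --- |
| `examples/table_summary.py` | demographic summary of the bundled 32-case clinical table (16 M / 16 F, mean age 50.6) |
| `examples/phantom_case.py` | phantom anatomy, truth masks, NIfTI export |
| `examples/registration_recovery.py` | rigid estimation recovers the planted 3° / 2 mm misalignment to ≈0.06° / 0.13 mm |
| `examples/cohort_analysis.py` | full 32-case cohort run: Wilcoxon, LASSO, stepwise, ROC, SVM/RF |

A thin CLI mirrors the pipeline for shell use:

```bash
edemarec simulate --n-cases 2 --seed 1 --out sim/
edemarec analyze --n-cases 32 --seed 1 --out run1/
edemarec heatmap --adc adc.nii.gz --edema edema.nii.gz \
                 --tumor tumor.nii.gz --tile-size 2 --threshold 2.408 \
                 --out heatmap.png --mask-out predicted.nii.gz
edemarec summarize
```

Sub-volume labelmaps are exported as NIfTI with integer codes
1 = `subedema_rec`, 2 = `subedema_no_rec`.

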