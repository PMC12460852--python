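# Methods

`edemarec` re-implements, as a tested pipeline, a registration-based
method for locating the sub-volume of glioblastoma (GBM) peritumoral
edema that is at high risk of harbouring recurrence, using first-order
histogram statistics of the apparent diffusion coefficient (ADC) map —
chiefly the ratio of the maximum to the mean ADC of a region
(`ratio_maxi_mean`, the Ratio-maxiADC/meanADC). This note records the
model, the synthetic study conditions, the numerical choices, and the
design decisions that were genuinely open.

## The analysis chain

1. **Registration.** The post-recurrence scan is aligned to the
   pre-recurrence anatomical grid by a 6-DOF rigid transform
   `y = R (x − c) + c + t` (rotation about a centre plus translation,
   world mm). Transforms compose, invert, and serialize as plain-text
   4×4 homogeneous matrices. `estimate_rigid` maximizes normalized
   cross-correlation (mean squares optional) with dense, non-stochastic
   sampling over a 3-level multi-resolution pyramid, so estimation is
   deterministic for a fixed configuration; the pipeline equally accepts
   precomputed transforms, which is how contour transfer is usually done
   in practice.
2. **Sub-volumes.** On the pre-recurrence grid, the edema mask is split
   into `subedema_rec = edema ∩ recurrent-tumor` and
   `subedema_no_rec = edema \ recurrent-tumor` — an exact voxel
   partition, checked on every labeling. Masks are resampled through
   transforms by linear interpolation of the indicator cut at 0.5
   (unbiased for half-voxel shifts). Cases whose recurrence misses the
   edema are flagged and excluded, mirroring the clinical inclusion
   criterion. The pre-recurrence tumor mask is *not* subtracted from
   the edema: the two structures are contoured as disjoint, and the
   generator guarantees disjointness.
3. **Features.** Eight per-ROI statistics of the ADC values inside a
   mask: mean; sample SD (N−1); max; min; median (mid-mean for even N);
   skewness g₁ = m₃/m₂^{3/2}; kurtosis m₄/m₂² (non-excess by default,
   the common radiomics convention — whether a given toolchain reports
   excess kurtosis is often unknowable, so a switch selects either);
   and max/mean. Skewness/kurtosis are reported as missing (NaN), not
   zero, when undefined (N < 3 or zero variance).
4. **Cohort statistics.** Each case contributes one `rec` and one
   `no_rec` row; the paired structure is used by the Wilcoxon
   signed-rank test and deliberately ignored by the classification
   models (the only reading consistent with an ROC over sub-volumes).
   Spearman's rho is the Pearson correlation of mid-ranks; p is exact
   (full permutation enumeration) for n ≤ 10, t-approximated above.
   Wilcoxon uses exact 2ⁿ sign enumeration for n ≤ 12 — valid under
   tied magnitudes, since signs remain iid conditional on the observed
   magnitudes — and a tie- and continuity-corrected normal
   approximation otherwise.
5. **Model selection.** An ℓ₁-penalized logistic screen minimizing
   `(1/n)·nll + λ‖β‖₁` on internally standardized features, solved by
   cyclic coordinate descent inside an IRLS loop with warm starts along
   a 100-point λ grid log-spaced over four decades below λ_max (the
   smallest λ with an all-zero penalized solution). KKT stationarity is
   verified at every reported solution (residual < 1e-6); λ_min
   minimizes the 10-fold stratified, seeded cross-validated deviance.
   Surviving features enter greedy forward stepwise logistic regression
   (likelihood-ratio entry test; Wald p and odds ratios reported from
   the final IRLS refit; `OR = exp(β)` by construction).
6. **Entry level for the chain.** The bare stepwise uses the
   conventional α = 0.05. The LASSO→stepwise *chain* defaults to
   α = 0.05/p over the original p-feature universe (0.00625 for the
   eight histogram features): entry p-values computed on screened
   candidates are selection-biased — a surviving noise feature is
   roughly the best-looking of the original universe — and measured
   false-entry rates at nominal 0.05 were ≈20% per screened candidate.
   The Bonferroni-style level restores approximately the intended
   family-wise false-entry rate. Sensitivity (planted-effect cohorts,
   exact-recovery rate per 100): α 0.05 → 67; 0.01 → 85–93;
   0.00625–0.005 → 92–98; 0.001 → 95 but the true feature starts being
   rejected.
7. **ROC.** Empirical ROC over all distinct score values; AUC equals
   the Mann–Whitney statistic U/(n₁n₀) with ties counted half (verified
   against brute-force pair counting). Orientation is chosen so the
   training AUC ≥ 0.5; the reported direction records whether low or
   high scores indicate recurrence. The Youden cutpoint maximizes
   sensitivity + specificity − 1; ties break toward higher specificity,
   then toward the more conservative threshold.
8. **Comparison classifiers.** RBF-SVM (C = 1, γ = scale, features
   standardized per training fold) and random forest (200 trees) under
   the same seeded stratified CV; the reported value is the mean of
   per-fold AUCs (per-fold because SVM decision scores are not
   comparable across folds). The contract is seeded reproducibility,
   not specific values.
9. **Location predictor (heatmap).** On the axial slice with the
   largest tumor area among slices that also carry edema (ties → lowest
   index), the edema is tiled in non-overlapping squares of 2, 2.5 or 3
   voxels per side, anchored at the edema bounding-box corner. All
   tiling happens on a 2× subdivided grid so fractional sizes are exact
   (2.5 voxels → 5 fine cells); the fine grid *replicates* each native
   voxel into its 2×2 cells rather than interpolating, because the tile
   statistic is a max and linear resampling at off-centre fine cells
   attenuates an isolated maximum by up to ~44%. A tile is evaluated
   iff at least half of its nominal area lies in the edema; its value is
   `(max ADC over the tile's edema cells) / (mean ADC over the whole
   edema ROI on that slice)`. The whole-ROI denominator is a design
   decision: a 4-voxel tile's internal max/mean is bounded near 1, so a
   ROI-level threshold like 2.408 can only be operative against the
   ROI mean. Tiles with value *below* the threshold (default 2.408) are
   predicted recurrence-prone; the opposite direction is configurable
   because the directionality of such a rule is a genuinely open choice
   — the default follows the convention that infiltrated edema lacks
   the free-water maxima of spared edema. Raising the threshold can
   only grow the predicted set (monotonicity, tested). Accuracy and
   Dice are computed over edema cells of the slice only, on the fine
   grid (identical to native scoring for integer tile sizes).

## Synthetic study conditions (what the generator emulates)

Real paired-timepoint GBM cohorts with contours cannot be
redistributed, so every stage is exercised on phantoms with analytic
ground truth:

* **Geometry.** Spherical tumor core (default radius 10 mm) inside a
  brain ellipsoid, a spherical-shell edema (thickness 8 mm), and an
  infiltrated angular wedge covering 40% of the shell by default. The
  wedge's angular edges wiggle with radius (±24° sinusoid, 4 mm
  wavelength, random phases) — infiltration fronts are irregular, and a
  straight boundary would make the location task unrealistically easy
  at coarse tile sizes. Cohorts jitter radius, thickness, wedge
  fraction and orientation per case; per-case seeds derive
  deterministically from one master seed.
* **Intensities** (10⁻⁶ mm²/s): background 750±50, tumor 600±80, edema
  shell 1500±150, infiltrated edema 1250±200 — plausible clinical
  magnitudes, all configurable, none treated as ground truth.
* **The max/mean contrast.** The sub-region designated high-ratio by
  `effect_direction` receives an admixture of high-ADC foci modelled as
  axially oriented single-voxel fluid tracks (think dilated
  perivascular spaces) on an exactly periodic, voxel-snapped in-plane
  lattice: areal fraction 0.25 (pitch 2 voxels), radius 0.45 mm,
  intensity = 5.5× the local component draw. Under the default
  `rec_lower_ratio` the foci sit in the *spared* shell, so the
  infiltrated wedge has the lower max/mean ratio and the below-threshold
  decision rule points at it; `rec_higher_ratio` moves the foci into
  the wedge instead. Two deliberate idealizations: the periodic
  spacing makes the focus texture homogeneous at tile scale (a
  Poisson scatter leaves gaps that larger tiles bridge better, which
  would invert the tile-size ordering the predictor is designed
  around), and the focus contrast is exaggerated (foci ≈ 8000×10⁻⁶
  mm²/s against a slice ROI mean ≈ 2500) so that the published-scale
  ROI-level threshold 2.408 is operative on the phantom slice — the
  ratio statistic only crosses such a threshold when regional maxima
  are several times the ROI mean.
* **Timepoints.** The recurrent tumor equals the old core plus the
  infiltrated wedge, filled with tumor-like ADC; the post-recurrence
  volumes are produced by resampling through the *inverse* of the
  planted rigid misalignment (default 3° about one axis + 2 mm
  translation — small enough for rigid recovery, large enough to
  matter), so that registering post to pre must recover exactly the
  planted transform.
* **What the phantom does not emulate.** No anatomy, bias fields, EPI
  distortion, partial-volume gradients, or scanner noise spectra; T1
  volumes carry no sub-region contrast (deliberately — the analysis
  should find nothing there). Passing tests therefore demonstrate the
  *mechanics* of the pipeline under a known, favourable
  signal-generating process, not clinical performance: with the default
  conditions the sub-volume contrast is strong (cohort AUC ≈ 1,
  quasi-separation in the logistic refit — flagged, and expected at
  these settings), while the published cohort-level numbers live on an
  inaccessible dataset and are treated as defaults and qualitative
  orderings only.

A separate tabular simulator (`simulate_feature_cohort`) draws the
eight features as unit normals with a single planted standardized shift
(default 1.2 SD on the max/mean ratio) for selection-recovery
experiments, where image generation would only add noise around the
same question.

## Numerical choices

* Voxel indexing is 0-based; world coordinates follow the NIfTI affine
  convention; resampling is by `scipy.ndimage.map_coordinates` (order
  1/0), exact on constants and degree-1 ramps at interior voxels; the
  fill value outside the source field of view is 0, and ROI statistics
  never include such voxels because ROIs are validated to lie on the
  volume grid.
* Euler angles are applied in Z-Y-X order about the volume centre.
* Coordinate descent tolerances: coefficient change < 1e-11 per sweep,
  objective change < 1e-12 relative per IRLS step; IRLS weights clipped
  at 1e-6. Separation (non-convergence or |β| > 10³ standardized) warns
  and truncates the λ path; the stepwise refit flags it and still
  reports.
* Grid defaults for phantoms are 64×64×44 voxels at 1 mm isotropic —
  large enough for ~20 000-voxel edema ROIs and stable tile statistics,
  small enough that 100-phantom experiments remain cheap; anisotropic
  spacings are exercised separately in unit tests.
* All randomness flows from explicit seeds (`numpy` Generator); one
  master seed feeds named substreams (cohort generation, CV folds,
  classifiers), and identical configurations rerun bit-identically.

## Known limitations

* The phantom's focus texture and contrast are calibrated idealizations
  (see above); the accuracy/Dice levels reported by the acceptance
  script characterize the pipeline under those conditions only.
* Registration estimation assumes mono-modal intensity similarity
  between timepoints; no deformable component models peritumoral mass
  effect.
* The heatmap is slice-based by design; a volumetric extension would
  change the ROI-mean denominator and the evaluability rule and is not
  provided.
* `wilcoxon_paired` reports W as the positive-rank sum; toolchains that
  report min(W⁺, W⁻) will show a different statistic at the same
  p-value.
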