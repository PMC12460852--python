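"""End-to-end orchestration: cohort analysis and single-case prediction.

``run_cohort_analysis`` composes the full chain on a cohort of cases
(synthetic or loaded): rigid alignment of the recurrent-tumor contour
onto the pre-recurrence grid, edema sub-volume construction, histogram
feature extraction, paired Wilcoxon tests, Spearman correlations, the
LASSO screen, forward stepwise logistic regression, ROC/Youden analysis
and the SVM/RF comparison — all seeded through one master seed with
named substreams, so reruns are bit-identical.

``run_case_prediction`` composes the location predictor for one case:
slice selection, tile heatmap, optional truth-based scoring, raster and
mask export.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models, stats
from .features import FEATURE_COLUMNS, extract_features
from .heatmap import (DEFAULT_THRESHOLD, TileHeatmap, evaluate_prediction,
                      render_heatmap, select_slice, tile_ratio_map,
                      write_prediction_mask)
from .phantom import PhantomCase, PhantomSpec, generate_cohort
from .registration import RigidTransform, estimate_rigid
from .subvolumes import define_subvolumes, dice, transform_mask, volume_mm3

log = logging.getLogger("edemarec")

# master-seed substreams, fixed offsets so every stage has its own stream
_SUBSTREAM = {"cohort": 0, "cv_folds": 1, "classifiers": 2}


def substream_seed(master_seed: int, name: str) -> int:
    return int((master_seed * 1_000_003 + _SUBSTREAM[name]) % (2 ** 31 - 1))


@dataclass
class RunConfig:
    """Configuration of a cohort run.

    ``registration`` is ``"supplied"`` (use the known/loaded transform,
    e.g. the phantom's ground-truth misalignment) or ``"estimate"``
    (intensity-based rigid estimation from the ADC volumes).
    """

    n_cases: int = 32
    seed: int = 1
    registration: str = "supplied"
    features: tuple = FEATURE_COLUMNS
    lasso_folds: int = 10
    alpha_entry: float | None = None   # None: 0.05 / n_features (chain default)
    tile_size: float = 2.0
    threshold: float = DEFAULT_THRESHOLD
    kurtosis_convention: str = "raw"
    output_dir: str | None = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["features"] = list(self.features)
        return json.dumps(d, indent=2)

    @staticmethod
    def from_json(text: str) -> "RunConfig":
        d = json.loads(text)
        d["features"] = tuple(d.get("features", FEATURE_COLUMNS))
        return RunConfig(**d)


@dataclass
class CohortSummary:
    n_cases: int
    n_male: int
    n_female: int
    mean_age: float                      # years, one decimal
    mean_volume_pre_mm3: float | None = None
    mean_volume_post_mm3: float | None = None
    exclusions: dict = field(default_factory=dict)


def summarize_cohort(records: pd.DataFrame) -> CohortSummary:
    """Counts and arithmetic means over a demographic table.

    Requires ``sex`` (M/F) and ``age`` columns; records with a non-empty
    ``exclusion_reason`` are tallied and removed before summarizing.
    Optional ``volume_pre_mm3`` / ``volume_post_mm3`` columns are
    averaged when present.
    """
    for col in ("sex", "age"):
        if col not in records.columns:
            raise ValueError(f"demographic table lacks required column {col!r}")
    exclusions: dict[str, int] = {}
    kept = records
    if "exclusion_reason" in records.columns:
        reason = records["exclusion_reason"].fillna("")
        excluded = reason != ""
        exclusions = reason[excluded].value_counts().to_dict()
        kept = records[~excluded]
    sex = kept["sex"].astype(str).str.upper()
    if not set(sex.unique()) <= {"M", "F"}:
        raise ValueError("sex column must contain only M/F")
    n = len(kept)
    summary = CohortSummary(
        n_cases=n,
        n_male=int((sex == "M").sum()),
        n_female=int((sex == "F").sum()),
        mean_age=round(float(kept["age"].mean()), 1),
        exclusions=exclusions)
    for col, attr in (("volume_pre_mm3", "mean_volume_pre_mm3"),
                      ("volume_post_mm3", "mean_volume_post_mm3")):
        if col in kept.columns:
            setattr(summary, attr, float(kept[col].mean()))
    return summary


# ---------------------------------------------------------------------------
# Cohort feature table


def build_cohort_table(cases: list[PhantomCase],
                       registration: str = "supplied",
                       kurtosis: str = "raw") -> tuple[pd.DataFrame, list[str]]:
    """Per-case sub-volume construction and feature extraction.

    Returns the cohort table (one rec and one no_rec row per usable
    case) and the list of skipped case ids with reasons logged.  A case
    is skipped when its recurrence does not intersect the edema or when
    any stage raises a validation error.
    """
    rows, skipped = [], []
    for case in cases:
        try:
            if registration == "supplied":
                T = case.spec.misalignment_transform()
            elif registration == "estimate":
                T = estimate_rigid(case.adc_pre, case.adc_post)
            else:
                raise ValueError(f"unknown registration mode {registration!r}")
            rec_on_pre = transform_mask(case.tumor_rec_native, T,
                                        case.adc_pre.grid)
            labeling = define_subvolumes(case.edema_pre, rec_on_pre,
                                         provenance=case.case_id)
            if labeling.rec_empty:
                raise ValueError("recurrence does not intersect the edema")
            for sub, mask, is_rec in (
                    ("rec", labeling.subedema_rec, 1),
                    ("no_rec", labeling.subedema_no_rec, 0)):
                feats = extract_features(case.adc_pre, mask, kurtosis=kurtosis)
                rows.append({
                    "case_id": case.case_id, "subvolume": sub, "label": is_rec,
                    "volume_mm3": volume_mm3(mask), **feats.to_dict()})
        except Exception as exc:
            log.warning("case %s skipped: %s", case.case_id, exc)
            skipped.append(case.case_id)
    if not rows:
        raise RuntimeError("all cases failed validation; nothing to analyze")
    return pd.DataFrame(rows), skipped


@dataclass
class CohortResult:
    table: pd.DataFrame
    skipped_cases: list[str]
    wilcoxon: pd.DataFrame
    spearman: pd.DataFrame
    lasso: models.LassoResult
    stepwise: models.StepwiseModel
    roc: stats.ROCCurve
    roc_feature: stats.ROCCurve | None
    comparison_aucs: dict[str, float]
    config: RunConfig

    def model_report(self) -> pd.DataFrame:
        """Per-feature report: LASSO keep/drop, stepwise p and OR."""
        rows = []
        step = {f: i for i, f in enumerate(self.stepwise.included_features)}
        for f in self.config.features:
            kept = f in self.lasso.selected_features
            if f in step:
                i = step[f]
                p = self.stepwise.p_values[i]
                orr = self.stepwise.odds_ratios[i]
            else:
                p = orr = float("nan")
            rows.append({"feature": f, "lasso": "keep" if kept else "drop",
                         "stepwise_p": p, "odds_ratio": orr})
        return pd.DataFrame(rows)


def run_cohort_analysis(config: RunConfig,
                        cases: list[PhantomCase] | None = None,
                        spec: PhantomSpec | None = None) -> CohortResult:
    """Execute the full cohort pipeline; deterministic given the seed."""
    if cases is None:
        spec = spec if spec is not None else PhantomSpec()
        cases = generate_cohort(config.n_cases, spec,
                                seed=substream_seed(config.seed, "cohort"))
    table, skipped = build_cohort_table(
        cases, registration=config.registration,
        kurtosis=config.kurtosis_convention)
    models.validate_cohort_table(table)
    features = [f for f in config.features if f in table.columns]

    rec = table[table.subvolume == "rec"].set_index("case_id")
    norec = table[table.subvolume == "no_rec"].set_index("case_id")
    shared = rec.index.intersection(norec.index)

    wil_rows, sp_rows = [], []
    for f in features:
        a = rec.loc[shared, f].to_numpy(dtype=float)
        b = norec.loc[shared, f].to_numpy(dtype=float)
        finite = np.isfinite(a) & np.isfinite(b)
        try:
            w, p = stats.wilcoxon_paired(a[finite], b[finite])
        except ValueError as exc:
            log.warning("wilcoxon on %s skipped: %s", f, exc)
            w = p = float("nan")
        wil_rows.append({"feature": f, "W": w, "p": p,
                         "n_pairs": int(finite.sum())})
        # correlation of the rec sub-volume's feature with its volume
        v = rec.loc[shared, "volume_mm3"].to_numpy(dtype=float)
        try:
            rho, sp = stats.spearman(a[finite], v[finite])
        except ValueError as exc:
            log.warning("spearman on %s skipped: %s", f, exc)
            rho = sp = float("nan")
        sp_rows.append({"feature": f, "rho": rho, "p": sp})
    wilcoxon = pd.DataFrame(wil_rows)
    spearman_tbl = pd.DataFrame(sp_rows)

    usable = [f for f in features
              if np.isfinite(table[f].to_numpy(dtype=float)).all()]
    lasso, stepwise = models.select_features_chain(
        table, usable, folds=config.lasso_folds,
        seed=substream_seed(config.seed, "cv_folds"),
        alpha_entry=config.alpha_entry)

    labels = table["label"].to_numpy(dtype=int)
    scores = stepwise.predicted_probability(table)
    if stepwise.intercept_only:
        roc = stats.ROCCurve(np.array([0.5]), np.array([1.0]), np.array([0.0]),
                             0.5, 0.5, 0.0, "above_positive")
    else:
        roc = stats.roc_analysis(scores, labels)
    roc_feature = None
    if len(stepwise.included_features) == 1:
        f = stepwise.included_features[0]
        roc_feature = stats.roc_analysis(table[f].to_numpy(dtype=float), labels)

    comparison = models.comparison_classifiers(
        table, usable, folds=config.lasso_folds,
        seed=substream_seed(config.seed, "classifiers"))

    result = CohortResult(table=table, skipped_cases=skipped,
                          wilcoxon=wilcoxon, spearman=spearman_tbl,
                          lasso=lasso, stepwise=stepwise, roc=roc,
                          roc_feature=roc_feature,
                          comparison_aucs=comparison, config=config)
    if config.output_dir:
        _write_bundle(result, Path(config.output_dir))
    return result


def _write_bundle(result: CohortResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(result.config.to_json())
    result.table.to_csv(outdir / "features.csv", index=False)
    result.wilcoxon.to_csv(outdir / "wilcoxon.csv", index=False)
    result.spearman.to_csv(outdir / "spearman.csv", index=False)
    result.model_report().to_csv(outdir / "model_report.csv", index=False)
    lines = [
        f"n rows: {len(result.table)} (skipped cases: {result.skipped_cases})",
        f"lasso selected: {result.lasso.selected_features} "
        f"(lambda_min = {result.lasso.lambda_min:.5g})",
        f"stepwise model: {result.stepwise.included_features}",
        f"model AUC: {result.roc.auc:.3f}"
        + (f"; feature-scale AUC {result.roc_feature.auc:.3f}, Youden "
           f"threshold {result.roc_feature.youden_threshold:.3f} "
           f"(sens {100 * result.roc_feature.youden_sensitivity:.1f}%, "
           f"spec {100 * result.roc_feature.youden_specificity:.1f}%)"
           if result.roc_feature else ""),
        f"comparison AUCs: {result.comparison_aucs}",
    ]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Single-case prediction


@dataclass
class CasePrediction:
    heatmap: TileHeatmap
    accuracy: float | None
    dice: float | None
    threshold: float
    slice_index: int


def run_case_prediction(adc, edema_pre, tumor_pre=None, truth_rec=None,
                        tile_size: float = 2.0,
                        threshold: float = DEFAULT_THRESHOLD,
                        direction: str = "below_positive",
                        slice_index: int | None = None,
                        raster_path=None, mask_path=None) -> CasePrediction:
    """Tile-heatmap prediction for one case.

    The slice is selected from the tumor mask when given, else must be
    passed explicitly.  Truth-based accuracy/Dice are reported only when
    ``truth_rec`` is supplied.
    """
    if slice_index is None:
        if tumor_pre is None:
            raise ValueError("need either slice_index or tumor_pre")
        slice_index = select_slice(tumor_pre, edema_pre)
    hm = tile_ratio_map(adc, edema_pre, slice_index, tile_size=tile_size,
                        threshold=threshold, direction=direction)
    acc = dc = None
    if truth_rec is not None:
        acc, dc = evaluate_prediction(hm, truth_rec, edema_pre)
    if raster_path is not None:
        render_heatmap(hm, adc, raster_path)
    if mask_path is not None:
        write_prediction_mask(hm, mask_path)
    return CasePrediction(heatmap=hm, accuracy=acc, dice=dc,
                          threshold=threshold, slice_index=slice_index)
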