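"""Full cohort analysis on a 32-case synthetic cohort.

Generates the cohort, aligns each recurrence contour onto the
pre-recurrence grid, builds the paired sub-volume feature table, and
runs the statistical chain: Wilcoxon paired tests, the cross-validated
LASSO screen, forward stepwise logistic regression, ROC analysis, and
the SVM / random-forest comparison.
"""

import warnings

from edemarec import RunConfig, run_cohort_analysis

warnings.filterwarnings("ignore")

result = run_cohort_analysis(RunConfig(n_cases=32, seed=1))

print(f"feature table: {len(result.table)} rows "
      f"({len(result.skipped_cases)} cases skipped)")
print("\npaired Wilcoxon (rec vs no_rec):")
print(result.wilcoxon.round(4).to_string(index=False))
print(f"\nLASSO keeps {result.lasso.selected_features} "
      f"(lambda_min = {result.lasso.lambda_min:.4g})")
print(f"stepwise model: {result.stepwise.included_features}")
print(result.stepwise.summary_frame().round(4).to_string(index=False))
print(f"\nmodel AUC {result.roc.auc:.3f}; "
      f"comparison AUCs {({k: round(v, 3) for k, v in result.comparison_aucs.items()})}")
if result.roc_feature is not None:
    r = result.roc_feature
    print(f"single-feature ROC: Youden threshold {r.youden_threshold:.3f} "
          f"(sens {100 * r.youden_sensitivity:.1f}%, "
          f"spec {100 * r.youden_specificity:.1f}%, direction {r.direction})")
# A p-value near zero for the max/mean ratio and an AUC near 1 say the
# planted sub-volume contrast is strong at these default phantom settings;
# on real cohorts the same numbers quantify how separable the two edema
# sub-volumes are.
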