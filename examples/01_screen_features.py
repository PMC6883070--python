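"""Full-data univariate screen of the bundled breast-FNA cohort.

For each of the 30 nuclear features, a single ROC analysis on all 569
lesions: Youden-optimal cutoff (both orientations scanned), sensitivity,
specificity and AUC.
"""

import samplecast as sc

cohort = sc.wdbc_cohort()
table = sc.screen_features(cohort).sort_values("yi", ascending=False)

print(table.head(8).to_string(index=False,
                              float_format=lambda v: f"{v:.3f}"))
print()
print(f"features with AUC >= 0.75: {(table.auc_oriented >= 0.75).sum()} / 30")
print(f"features with YI  >= 0.50: {(table.yi >= 0.5).sum()} / 30")
print()
print("A feature with YI near 0 carries no univariate signal; the counts "
      "above say most nuclear features separate malignant from benign "
      "lesions on their own.")
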