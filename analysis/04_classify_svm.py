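#!/usr/bin/env python
"""SVM stratification of the cohort on its bioenergetic profiles.

For each task (control vs. all disease groups; sALS vs. PLS) this runs
the 1120-point hyperparameter grid under stratified 10-fold
cross-validation, evaluates the accuracy-selected model, and writes the
grid table, mean/fold ROC curves, and the confusion panel with CIs to
results/svm/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from fibroenergetics import classify as clf
from fibroenergetics.core import assemble_feature_matrix, read_cohort

SEED = 1


def main() -> None:
    out = ROOT / "results" / "svm"
    out.mkdir(parents=True, exist_ok=True)
    profiles = pd.read_csv(ROOT / "results" / "profiles.csv",
                           dtype={"line_id": str}).dropna()
    cohort = read_cohort(ROOT / "results" / "cohort")
    X, y = assemble_feature_matrix(profiles, lines=cohort.lines)

    for task in ("control-vs-disease", "sals-vs-pls"):
        mask, yb = clf.make_task(y.to_numpy(), task)
        Xt = X.to_numpy()[mask]
        search = clf.cross_validate_grid(Xt, yb, k=10, seed=SEED)
        report = clf.evaluate_best(Xt, yb, search.best_point, k=10, seed=SEED,
                                   task=task)
        stem = task.replace("-", "_")
        search.accuracy_table.to_csv(out / f"grid_{stem}.csv", index=False)
        pd.DataFrame({"fpr": report.fpr_grid, "tpr": report.mean_tpr}
                     ).to_csv(out / f"roc_mean_{stem}.csv", index=False)
        with open(out / f"cv_report_{stem}.json", "w") as fh:
            json.dump({**report.summary(),
                       "fold_aucs": report.fold_aucs,
                       "pooled_confusion": report.pooled_confusion}, fh, indent=2)
        best = search.best_point
        print(f"\n{task} (n={len(yb)}):")
        print(f"  best model: {best.kernel} kernel, C={best.C:g}, "
              f"gamma={best.gamma:.4g}, class_weight={best.class_weight}")
        print(f"  mean CV accuracy {100 * search.best_mean_accuracy:.1f}%, "
              f"mean-ROC AUC {report.auc_mean_curve:.3f}")
        panel = report.panel.set_index("metric")
        for metric in ("sensitivity", "specificity", "ppv", "npv"):
            row = panel.loc[metric]
            print(f"  {metric:12s} {row['value']:5.1f}% "
                  f"(CI {row['ci_low']:.1f}-{row['ci_high']:.1f})")


if __name__ == "__main__":
    main()
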