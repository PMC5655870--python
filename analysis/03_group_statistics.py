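#!/usr/bin/env python
"""Nonparametric group comparisons, effect sizes, and correlations.

Runs the full battery on results/profiles.csv: the normality gate,
Kruskal-Wallis + Dunn per feature, percent-of-control effect sizes with
bootstrap CIs, Spearman correlations over the seven canonical feature
pairs with joint BH-FDR control, and the median-split stratification of
sALS lines against their clinical covariates. Writes
results/stats/*.csv and prints the headline findings.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from fibroenergetics import stats as fstats
from fibroenergetics.core import FEATURES, assemble_feature_matrix, read_cohort
from fibroenergetics.synthesize import SPEARMAN_PAIRS

SEED = 1
MEDIAN_SPLIT_FEATURES = ("tmrm", "ecar_aarot", "ocr_oligo_sens")
CLINICAL = ("age_onset", "progression_rate", "fvc_pct")


def main() -> None:
    out = ROOT / "results" / "stats"
    out.mkdir(parents=True, exist_ok=True)
    profiles = pd.read_csv(ROOT / "results" / "profiles.csv",
                           dtype={"line_id": str}).dropna()
    cohort = read_cohort(ROOT / "results" / "cohort")
    X, y = assemble_feature_matrix(profiles, lines=cohort.lines)

    scan, nonparametric = fstats.normality_scan(X)
    scan.to_csv(out / "normality_scan.csv", index=False)
    print(f"normality gate: {int((scan['p'] < 0.05).sum())}/12 features reject "
          f"normality -> {'nonparametric' if nonparametric else 'parametric'} battery")

    report, comparisons = fstats.group_comparison_table(X, y, seed=SEED)
    report.to_csv(out / "stats_report.csv", index=False)
    sig = report[(report["dunn_p"] < 0.05)
                 & ((report["group_a"] == "control")
                    | (report["group_b"] == "control"))]
    print("\nfeatures different from control (Dunn p < 0.05):")
    for _, row in sig.iterrows():
        other = row["group_b"] if row["group_a"] == "control" else row["group_a"]
        print(f"  {row['feature']:16s} {other:8s} "
              f"{row['percent_of_reference']:6.1f}% of control "
              f"(CI {row['ci_low']:.1f}-{row['ci_high']:.1f}, p={row['dunn_p']:.2g})")

    prof = X.copy()
    prof["group"] = y
    corr = fstats.spearman_bh(prof, SPEARMAN_PAIRS, fdr=0.05, family="joint")
    corr.to_csv(out / "correlations.csv", index=False)
    print("\nsignificant rank correlations (BH-FDR < 0.05):")
    for _, row in corr[corr["significant"]].iterrows():
        print(f"  {row['group']:8s} {row['feature_a']} ~ {row['feature_b']}: "
              f"R = {row['r']:+.3f}")

    lines = cohort.lines.set_index("line_id")
    sals = X[y == "sALS"]
    split_rows = []
    for feature in MEDIAN_SPLIT_FEATURES:
        for clin in CLINICAL:
            clinical = lines.loc[sals.index, clin]
            res = fstats.median_split(sals[feature], clinical)
            split_rows.append({"feature": feature, "clinical": clin,
                               "pct_difference": res.percent_difference,
                               "u": res.u_statistic, "p": res.p})
    splits = pd.DataFrame(split_rows)
    splits.to_csv(out / "median_split.csv", index=False)
    print("\nmedian-split comparisons (sALS, above vs below median):")
    for _, row in splits.iterrows():
        print(f"  {row['feature']} x {row['clinical']}: "
              f"{row['pct_difference']:+.1f}% (p={row['p']:.2g})")


if __name__ == "__main__":
    main()
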