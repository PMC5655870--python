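"""Nonparametric statistical battery for bioenergetic feature matrices.

The analysis convention for these assay data, none of which pass an
omnibus normality test, is fully nonparametric:

* D'Agostino-Pearson K^2 normality scan gating the parametric/
  nonparametric choice,
* Kruskal-Wallis omnibus across the four groups with Dunn's z-test as
  post hoc (tie-corrected), post hoc reported only under a significant
  omnibus,
* effect sizes as percent-of-reference (mean ratio x100) with bootstrap
  percentile confidence intervals,
* Spearman rank correlations with Benjamini-Hochberg FDR control over
  the joint family of (feature pair x group) hypotheses,
* median-split stratification of a feature against clinical covariates
  via two-sided Mann-Whitney U.

All tests are two-sided at alpha = 0.05 unless configured otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normality_scan",
    "kruskal_dunn",
    "GroupComparison",
    "percent_of_reference",
    "spearman_bh",
    "median_split",
    "MedianSplitResult",
    "group_comparison_table",
]

ALPHA = 0.05
#: minimum group size for a valid D'Agostino-Pearson statistic
NORMALITY_N_FLOOR = 20


def normality_scan(X: pd.DataFrame, alpha: float = ALPHA) -> tuple[pd.DataFrame, bool]:
    """Per-feature D'Agostino-Pearson omnibus normality test.

    Returns ``(table, nonparametric)`` where the table has one row per
    feature (n, K^2 statistic, p, tested flag) and ``nonparametric`` is
    True when any tested feature rejects normality at ``alpha`` — the
    gate that sends the downstream battery to rank-based tests. Features
    with n below the statistic's validity floor (20) or zero variance are
    flagged untested.
    """
    rows = []
    nonparametric = False
    for feature in X.columns:
        values = X[feature].dropna().to_numpy(float)
        n = len(values)
        if n < NORMALITY_N_FLOOR or np.ptp(values) == 0:
            rows.append({"feature": feature, "n": n, "k2": np.nan,
                         "p": np.nan, "tested": False})
            continue
        k2, p = sps.normaltest(values)
        nonparametric = nonparametric or (p < alpha)
        rows.append({"feature": feature, "n": n, "k2": k2, "p": p, "tested": True})
    return pd.DataFrame(rows), nonparametric


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray,
                   adjust: str | None = None) -> pd.DataFrame:
    """Dunn's z-test on mean ranks with tie-corrected variance.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; p two-sided normal.
    ``adjust='bonferroni'`` multiplies p by the number of pairs.
    """
    ranks = sps.rankdata(values)
    N = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    groups = pd.unique(labels)
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    rows = []
    pairs = list(itertools.combinations(groups, 2))
    for a, b in pairs:
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * len(pairs))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p})
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Omnibus + post hoc comparison of one feature across groups."""

    feature: str
    kw_statistic: float
    kw_p: float
    dunn: pd.DataFrame          # columns group_a, group_b, z, p
    posthoc_reported: bool      # post hoc only meaningful when omnibus < alpha
    percent_of_reference: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["group", "reference", "percent", "ci_low", "ci_high"]))


def kruskal_dunn(values, labels, alpha: float = ALPHA,
                 dunn_adjust: str | None = None,
                 feature: str = "") -> GroupComparison:
    """Kruskal-Wallis omnibus followed by Dunn's pairwise post hoc.

    ``dunn_adjust`` is None by default (Dunn's z-based p as-is); pass
    ``'bonferroni'`` to additionally correct across the post hoc family.
    Requires at least two groups with n >= 2 each.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis requires at least two groups")
    samples = [values[labels == g] for g in groups]
    if min(len(s) for s in samples) < 2:
        raise ValueError("every group needs n >= 2")
    if np.ptp(values) == 0:  # scipy rejects the all-identical degenerate case
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = sps.kruskal(*samples)
    dunn = _dunn_pairwise(values, labels, adjust=dunn_adjust)
    return GroupComparison(feature=feature, kw_statistic=float(kw_stat),
                           kw_p=float(kw_p), dunn=dunn,
                           posthoc_reported=bool(kw_p < alpha))


def percent_of_reference(values_a, values_b, n_boot: int = 10_000,
                         seed: int = 0, paired: bool = False
                         ) -> tuple[float, float, float]:
    """mean(a)/mean(b) x 100 with a bootstrap percentile 95% CI.

    Both groups are resampled with replacement ``n_boot`` times; the CI
    is the 2.5/97.5 percentile of the resampled percent. Independent
    group resampling is the default (the two patient groups are
    independent samples); ``paired=True`` shares the resampled indices
    between equal-length groups, appropriate for paired designs (there
    the CI of a constant elementwise ratio collapses to a point). The
    reference group mean must be nonzero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("percent_of_reference requires non-empty groups")
    if b.mean() == 0:
        raise ValueError("reference group mean is zero")
    point = a.mean() / b.mean() * 100.0
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, (n_boot, a.size))
    if paired:
        if a.size != b.size:
            raise ValueError("paired resampling requires equal group sizes")
        idx_b = idx_a
    else:
        idx_b = rng.integers(0, b.size, (n_boot, b.size))
    boot = a[idx_a].mean(axis=1) / b[idx_b].mean(axis=1) * 100.0
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return float(point), float(lo), float(hi)


def spearman_bh(profiles: pd.DataFrame, pairs, groups=None, fdr: float = 0.05,
                family: str = "joint") -> pd.DataFrame:
    """Spearman correlations per (feature pair, group) with BH-FDR flags.

    ``profiles`` needs a ``group`` column plus the feature columns.
    ``family`` controls the BH correction family: ``'joint'`` adjusts all
    (pair x group) p-values together (the conservative reading),
    ``'per_group'`` adjusts within each group. Pairs with group n < 4
    get an undefined p and are excluded from the correction. Ties are
    handled with average ranks (scipy's convention).
    """
    if family not in ("joint", "per_group"):
        raise ValueError("family must be 'joint' or 'per_group'")
    groups = list(groups) if groups is not None else list(pd.unique(profiles["group"]))
    rows = []
    for f1, f2 in pairs:
        for g in groups:
            sub = profiles.loc[profiles["group"] == g, [f1, f2]].dropna()
            if len(sub) < 4:
                rows.append({"feature_a": f1, "feature_b": f2, "group": g,
                             "n": len(sub), "r": np.nan, "p": np.nan})
                continue
            res = sps.spearmanr(sub[f1], sub[f2])
            rows.append({"feature_a": f1, "feature_b": f2, "group": g,
                         "n": len(sub), "r": float(res.statistic),
                         "p": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["significant"] = False
    if family == "joint":
        mask = out["p"].notna()
        if mask.any():
            rej = multipletests(out.loc[mask, "p"], alpha=fdr, method="fdr_bh")[0]
            out.loc[mask, "significant"] = rej
    else:
        for g in groups:
            mask = (out["group"] == g) & out["p"].notna()
            if mask.any():
                rej = multipletests(out.loc[mask, "p"], alpha=fdr, method="fdr_bh")[0]
                out.loc[mask, "significant"] = rej
    return out


@dataclass
class MedianSplitResult:
    """Below-/above-median stratification compared on a clinical variable."""

    n_lower: int
    n_upper: int
    lower_index: np.ndarray
    upper_index: np.ndarray
    mean_lower: float
    mean_upper: float
    percent_difference: float   # (upper - lower) / lower x 100
    u_statistic: float
    p: float


def median_split(feature_values, clinical_values) -> MedianSplitResult:
    """Split lines at the feature median and Mann-Whitney the clinical values.

    Pairs with a missing clinical value are dropped first. The split puts
    ties at the median — and, for odd n, the median line itself — in the
    lower half, giving halves of size ceil(n/2) and floor(n/2). The
    clinical variable is compared across halves with a two-sided
    Mann-Whitney U test; the effect is the percent difference of the
    upper-half mean relative to the lower-half mean.
    """
    feature_values = np.asarray(feature_values, dtype=float)
    clinical_values = np.asarray(clinical_values, dtype=float)
    keep = ~np.isnan(clinical_values) & ~np.isnan(feature_values)
    feature_values, clinical_values = feature_values[keep], clinical_values[keep]
    kept_index = np.flatnonzero(keep)
    n = len(feature_values)
    if n < 4:
        raise ValueError("median split requires n >= 4 non-missing pairs")
    if np.ptp(feature_values) == 0:
        raise ValueError("all feature values equal; no split possible")
    order = np.argsort(feature_values, kind="mergesort")
    n_lower = (n + 1) // 2
    lower, upper = order[:n_lower], order[n_lower:]
    clin_lo, clin_hi = clinical_values[lower], clinical_values[upper]
    u, p = sps.mannwhitneyu(clin_hi, clin_lo, alternative="two-sided")
    mean_lo, mean_hi = clin_lo.mean(), clin_hi.mean()
    pct = (mean_hi - mean_lo) / mean_lo * 100.0 if mean_lo != 0 else np.nan
    return MedianSplitResult(
        n_lower=int(n_lower), n_upper=int(n - n_lower),
        lower_index=kept_index[lower], upper_index=kept_index[upper],
        mean_lower=float(mean_lo), mean_upper=float(mean_hi),
        percent_difference=float(pct), u_statistic=float(u), p=float(p),
    )


def group_comparison_table(X: pd.DataFrame, y: pd.Series,
                           reference: str = "control",
                           n_boot: int = 10_000, seed: int = 0,
                           alpha: float = ALPHA) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Run the full battery for every feature of a matrix.

    For each feature: Kruskal-Wallis + Dunn across all groups, and
    percent-of-reference (with bootstrap CI) of each non-reference group
    against ``reference``. Returns a tidy one-row-per-(feature, pair)
    report and the full :class:`GroupComparison` objects.
    """
    labels = y.to_numpy()
    comparisons = []
    rows = []
    for k, feature in enumerate(X.columns):
        values = X[feature].to_numpy(float)
        comp = kruskal_dunn(values, labels, alpha=alpha, feature=feature)
        pct_rows = []
        ref_values = values[labels == reference]
        for j, g in enumerate(g for g in pd.unique(labels) if g != reference):
            pct, lo, hi = percent_of_reference(
                values[labels == g], ref_values, n_boot=n_boot,
                seed=seed + 1000 * k + j)
            pct_rows.append({"group": g, "reference": reference,
                             "percent": pct, "ci_low": lo, "ci_high": hi})
        comp.percent_of_reference = pd.DataFrame(pct_rows)
        comparisons.append(comp)
        for _, dr in comp.dunn.iterrows():
            prow = next((r for r in pct_rows
                         if {dr["group_a"], dr["group_b"]} == {r["group"], reference}),
                        None)
            rows.append({
                "feature": feature, "group_a": dr["group_a"], "group_b": dr["group_b"],
                "kw_statistic": comp.kw_statistic, "kw_p": comp.kw_p,
                "dunn_z": dr["z"],
                "dunn_p": dr["p"] if comp.posthoc_reported else np.nan,
                "percent_of_reference": prow["percent"] if prow else np.nan,
                "ci_low": prow["ci_low"] if prow else np.nan,
                "ci_high": prow["ci_high"] if prow else np.nan,
            })
    return pd.DataFrame(rows), comparisons
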