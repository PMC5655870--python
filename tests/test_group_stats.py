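"""Nonparametric battery: normality gate, KW/Dunn, effect sizes, BH, splits."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fibroenergetics import stats as fstats


class TestNormalityScan:
    def test_normal_draws_pass_and_lognormal_fail(self):
        rng = np.random.default_rng(40)
        X = pd.DataFrame({"gaussian": rng.normal(size=5000),
                          "skewed": rng.lognormal(sigma=0.8, size=5000)})
        table, nonparametric = fstats.normality_scan(X)
        table = table.set_index("feature")
        assert table.loc["gaussian", "p"] > 0.05
        assert table.loc["skewed", "p"] < 0.05
        assert nonparametric

    def test_constant_and_small_samples_flagged_untested(self):
        X = pd.DataFrame({"constant": np.ones(50),
                          "tiny": np.r_[np.random.default_rng(1).normal(size=10),
                                        [np.nan] * 40]})
        table, nonparametric = fstats.normality_scan(X)
        assert not table["tested"].any()
        assert not nonparametric


class TestKruskalDunn:
    def test_hand_computed_nine_value_oracle(self):
        """Three groups of three with ranks 1-9: H and Dunn z by hand.

        Mean ranks 2, 5, 8; H = 12/(9*10) * 3*((2-5)^2+0+(8-5)^2) = 7.2;
        adjacent z = 3/sqrt(7.5*2/3) = 1.3416 (p = 0.1797, not significant),
        extreme z = 6/sqrt(5) = 2.6833 (p = 0.00729).
        """
        values = np.array([1, 2, 3, 101, 102, 103, 201, 202, 203], float)
        labels = np.repeat(["a", "b", "c"], 3)
        comp = fstats.kruskal_dunn(values, labels)
        assert comp.kw_statistic == pytest.approx(7.2)
        assert comp.kw_p == pytest.approx(0.02732, abs=1e-4)
        assert comp.posthoc_reported
        dunn = {frozenset((r["group_a"], r["group_b"])): r
                for _, r in comp.dunn.iterrows()}
        assert abs(dunn[frozenset(("a", "c"))]["z"]) == pytest.approx(2.68328, abs=1e-4)
        assert dunn[frozenset(("a", "c"))]["p"] == pytest.approx(0.00729, abs=1e-4)
        assert abs(dunn[frozenset(("a", "b"))]["z"]) == pytest.approx(1.34164, abs=1e-4)
        assert dunn[frozenset(("a", "b"))]["p"] == pytest.approx(0.17971, abs=1e-4)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(41)
        values = rng.normal(size=60)
        labels = np.repeat(["x", "y", "z"], 20)
        a = fstats.kruskal_dunn(values, labels)
        mapping = {"x": "z", "y": "x", "z": "y"}
        b = fstats.kruskal_dunn(values, np.array([mapping[l] for l in labels]))
        pa = {frozenset((mapping[r["group_a"]], mapping[r["group_b"]])): r["p"]
              for _, r in a.dunn.iterrows()}
        pb = {frozenset((r["group_a"], r["group_b"])): r["p"]
              for _, r in b.dunn.iterrows()}
        for pair in pb:
            assert pb[pair] == pytest.approx(pa[pair], rel=1e-12)

    def test_identical_groups_give_zero_statistic(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = np.repeat(["a", "b"], 3)
        comp = fstats.kruskal_dunn(values, labels)
        assert comp.kw_statistic == pytest.approx(0.0, abs=1e-12)
        assert not comp.posthoc_reported

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            fstats.kruskal_dunn([1.0, 2.0, 3.0], ["a", "a", "a"])

    def test_bonferroni_option_scales_p(self):
        values = np.array([1, 2, 3, 101, 102, 103, 201, 202, 203], float)
        labels = np.repeat(["a", "b", "c"], 3)
        plain = fstats.kruskal_dunn(values, labels)
        adj = fstats.kruskal_dunn(values, labels, dunn_adjust="bonferroni")
        assert np.allclose(np.minimum(plain.dunn["p"] * 3, 1.0), adj.dunn["p"])


def brute_force_bh(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Literal step-up definition: largest k with p_(k) <= k/m * alpha;
    reject the k smallest."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    sorted_p = pvals[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k / m * alpha:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestBenjaminiHochberg:
    def test_statsmodels_matches_brute_force_exhaustively(self):
        """The BH used by the pipeline equals the step-up definition on an
        exhaustive grid of p-vectors up to length 6."""
        from statsmodels.stats.multitest import multipletests
        grid = [0.001, 0.012, 0.04, 0.2, 1.0]
        for m in range(1, 7):
            for combo in itertools.combinations_with_replacement(grid, m):
                p = np.array(combo)
                expected = brute_force_bh(p, 0.05)
                got = multipletests(p, alpha=0.05, method="fdr_bh")[0]
                assert (expected == got).all(), combo

    def test_worked_example(self):
        p = np.array([0.001, 0.01, 0.02, 0.9])
        assert brute_force_bh(p, 0.05).tolist() == [True, True, True, False]


class TestPercentOfReference:
    def test_reported_percent_from_group_means(self):
        # one-point groups make the estimate the plain ratio of means
        pct, _, _ = fstats.percent_of_reference([948.3], [743.4], n_boot=10)
        assert round(pct, 1) == 127.6

    def test_identity_is_exactly_100(self):
        a = np.array([3.0, 5.0, 9.0])
        pct, lo, hi = fstats.percent_of_reference(a, a, n_boot=2000, seed=1)
        assert pct == 100.0
        assert lo <= 100.0 <= hi

    def test_doubled_group_is_exactly_200(self):
        rng = np.random.default_rng(42)
        b = rng.lognormal(size=200)
        # paired design: a is b elementwise doubled, so every paired
        # resample has ratio exactly 200 and the CI collapses
        pct, lo, hi = fstats.percent_of_reference(2 * b, b, n_boot=200, seed=2,
                                                  paired=True)
        assert pct == pytest.approx(200.0)
        assert lo == pytest.approx(200.0, abs=2.0)
        assert hi == pytest.approx(200.0, abs=2.0)
        # independent resampling still centers on 200
        pct, lo, hi = fstats.percent_of_reference(2 * b, b, n_boot=2000, seed=2)
        assert lo <= 200.0 <= hi

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fstats.percent_of_reference([], [1.0], n_boot=10)


class TestSpearmanBh:
    def test_perfect_monotone_extremes(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [1, 2, 3, 4],
                           "z": [4, 3, 2, 1], "group": "g"})
        out = fstats.spearman_bh(df, [("x", "y"), ("x", "z")])
        out = out.set_index("feature_b")
        assert out.loc["y", "r"] == pytest.approx(1.0)
        assert out.loc["z", "r"] == pytest.approx(-1.0)

    def test_joint_family_is_more_conservative_than_per_group(self):
        rng = np.random.default_rng(43)
        frames = []
        for g in ("g1", "g2", "g3", "g4"):
            x = rng.normal(size=30)
            frames.append(pd.DataFrame({
                "x": x,
                # strongly correlated only in g1
                "y": x + rng.normal(scale=0.2 if g == "g1" else 5.0, size=30),
                "w": rng.normal(size=30),
                "group": g}))
        df = pd.concat(frames)
        joint = fstats.spearman_bh(df, [("x", "y"), ("x", "w")], family="joint")
        per = fstats.spearman_bh(df, [("x", "y"), ("x", "w")], family="per_group")
        assert joint["significant"].sum() <= per["significant"].sum() + 1
        g1 = joint[(joint["group"] == "g1") & (joint["feature_b"] == "y")]
        assert bool(g1["significant"].iloc[0])

    def test_small_groups_get_undefined_p(self):
        df = pd.DataFrame({"x": [1, 2, 3], "y": [1, 2, 3], "group": "tiny"})
        out = fstats.spearman_bh(df, [("x", "y")])
        assert np.isnan(out["p"].iloc[0])
        assert not out["significant"].iloc[0]


def test_default_cohort_reproduces_qualitative_group_pattern():
    """On a default synthetic cohort the battery recovers the expected
    biology: TMRM, baseline OCR, and baseline ECAR elevated in sALS and
    PLS vs control; mitochondrial content (MTG) reduced in PLS."""
    from fibroenergetics import features as feat
    from fibroenergetics import synthesize as syn
    from fibroenergetics.core import assemble_feature_matrix

    cohort, _ = syn.generate_cohort(syn.default_config(seed=7))
    profiles, _ = feat.build_profiles(cohort)
    X, y = assemble_feature_matrix(profiles.dropna(), lines=cohort.lines)
    labels = y.to_numpy()

    def dunn_p(comp, a, b):
        for _, row in comp.dunn.iterrows():
            if {row["group_a"], row["group_b"]} == {a, b}:
                return row["p"]
        raise KeyError((a, b))

    for feature, group, direction in [("tmrm", "sALS", 1), ("tmrm", "PLS", 1),
                                      ("ocr_base", "sALS", 1), ("ocr_base", "PLS", 1),
                                      ("ecar_base", "sALS", 1), ("ecar_base", "PLS", 1),
                                      ("mtg", "PLS", -1)]:
        values = X[feature].to_numpy()
        comp = fstats.kruskal_dunn(values, labels, feature=feature)
        assert comp.kw_p < 0.05, feature
        assert dunn_p(comp, group, "control") < 0.05, (feature, group)
        delta = values[labels == group].mean() - values[labels == "control"].mean()
        assert np.sign(delta) == direction, (feature, group)


class TestMedianSplit:
    def test_worked_example(self):
        res = fstats.median_split([1, 2, 3, 4], [10, 10, 20, 20])
        assert (res.n_lower, res.n_upper) == (2, 2)
        assert res.mean_lower == 10 and res.mean_upper == 20
        assert res.percent_difference == pytest.approx(100.0)

    def test_identical_clinical_values_maximal_p(self):
        res = fstats.median_split([1, 2, 3, 4, 5, 6], [7, 7, 7, 7, 7, 7])
        assert res.p == pytest.approx(1.0)

    def test_odd_n_puts_median_in_lower_half(self):
        res = fstats.median_split([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert (res.n_lower, res.n_upper) == (3, 2)

    def test_all_equal_feature_rejected(self):
        with pytest.raises(ValueError, match="split"):
            fstats.median_split([2, 2, 2, 2], [1, 2, 3, 4])

    def test_missing_clinical_values_dropped_pairwise(self):
        res = fstats.median_split([1, 2, 3, 4, 5, 6],
                                  [10, np.nan, 10, 20, np.nan, 20])
        assert res.n_lower + res.n_upper == 4

    def test_detects_real_difference(self):
        rng = np.random.default_rng(44)
        feature = np.r_[rng.normal(0, 1, 50), rng.normal(5, 1, 50)]
        clinical = np.r_[rng.normal(10, 1, 50), rng.normal(20, 1, 50)]
        res = fstats.median_split(feature, clinical)
        assert res.p < 1e-6
        assert res.percent_difference > 50
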