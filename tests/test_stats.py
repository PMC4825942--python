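"""Biomarker statistics against independent oracles and closed forms."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from methylmark.stats import (
    classify_severity,
    correlation,
    dunn_posthoc,
    kruskal_wallis,
    partial_correlation,
    partial_correlation_from_r,
    roc,
    ttest_power,
)


# ---------------------------------------------------------------------------
# oracles


def kw_h_oracle(groups):
    """Tie-corrected Kruskal-Wallis H from first principles (rank formula)."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank, 1-based
        i = j
    bounds = np.cumsum([0] + [len(g) for g in groups])
    h = 12.0 / (n * (n + 1)) * sum(
        len(g) * (ranks[bounds[k]:bounds[k + 1]].mean() - (n + 1) / 2.0) ** 2
        for k, g in enumerate(groups)
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def auc_trapezoid(points):
    """Trapezoidal area under the (1-specificity, sensitivity) curve."""
    fpr = np.concatenate([[0.0], 1.0 - points["specificity"].to_numpy()])
    tpr = np.concatenate([[0.0], points["sensitivity"].to_numpy()])
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


# ---------------------------------------------------------------------------
# Kruskal-Wallis / Dunn


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        res = kruskal_wallis([1.0, 1.0], [1.0], [1.0, 1.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_rank_oracle_on_small_instances(self, rng):
        """H agrees with the brute-force rank formula on all 3-group size
        combinations up to 5, with random (tied and untied) data."""
        for sizes in itertools.product(range(1, 6), repeat=3):
            if sum(sizes) < 3:
                continue
            groups = [np.round(rng.uniform(0, 4, s), 0) for s in sizes]  # forces ties
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            res = kruskal_wallis(*groups)
            assert res.statistic == pytest.approx(kw_h_oracle(groups), rel=1e-10)

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(i, 1, 8) for i in range(3)]
        h1 = kruskal_wallis(*groups).statistic
        h2 = kruskal_wallis(*[np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)

    def test_study_cohort_three_group_comparison_significant(self, study_cohort):
        """The three-group methylation difference is significant at the
        fixture seed and highly significant in the typical draw."""
        groups = [g["methylation_pct"].to_numpy()
                  for _, g in study_cohort.groupby("group")]
        assert kruskal_wallis(*groups).p_value < 0.05
        from methylmark import synthetic as syn

        ps = []
        for seed in range(15):
            subj = syn.generate_cohort(syn.study_cohort_config(seed=seed))
            gs = [g["methylation_pct"].to_numpy() for _, g in subj.groupby("group")]
            ps.append(kruskal_wallis(*gs).p_value)
        assert np.median(ps) < 0.001


class TestDunn:
    def test_two_groups_equal_unadjusted_z_test(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        (res,) = dunn_posthoc([a, b])
        assert res.p_value == pytest.approx(res.extra["p_unadjusted"])

    def test_z_matches_closed_form_on_hand_data(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]),
                  np.array([7.0, 8.0, 9.0])]
        results = dunn_posthoc(groups, adjustment="none")
        n = 9
        sigma2 = n * (n + 1) / 12.0  # no ties
        # mean ranks are 2, 5, 8
        expected_z01 = (2 - 5) / math.sqrt(sigma2 * (2 / 3))
        assert results[0].statistic == pytest.approx(expected_z01)

    def test_adjusted_p_at_least_unadjusted_and_capped(self, rng):
        groups = [rng.normal(i * 0.1, 1, 15) for i in range(4)]
        for res in dunn_posthoc(groups):
            assert res.p_value >= res.extra["p_unadjusted"]
            assert res.p_value <= 1.0

    def test_study_cohort_pairwise_pattern(self):
        """Across seeds, AD typically separates from MCI while MCI and
        control never do, and AD always ranks below control.  (The AD vs
        control contrast is underpowered at n=10 controls with a Bonferroni
        triple, so only its direction is stable.)"""
        from methylmark import synthetic as syn

        ad_mci, mci_ctl_ns, ad_ctl_direction = 0, 0, 0
        n_seeds = 15
        for seed in range(n_seeds):
            subj = syn.generate_cohort(syn.study_cohort_config(seed=seed))
            by_group = {g: df["methylation_pct"].to_numpy()
                        for g, df in subj.groupby("group")}
            results = {r.name: r for r in dunn_posthoc(by_group)}
            ad_mci += results["dunn:AD_vs_MCI"].p_value < 0.05
            mci_ctl_ns += results["dunn:MCI_vs_control"].p_value > 0.05
            ad_ctl_direction += results["dunn:AD_vs_control"].statistic < 0
        assert ad_mci >= n_seeds // 2 + 1
        assert mci_ctl_ns == n_seeds
        assert ad_ctl_direction == n_seeds

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dunn_posthoc([np.array([1.0]), np.array([])])


# ---------------------------------------------------------------------------
# correlation


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert correlation(x, x).statistic == pytest.approx(1.0)

    def test_spearman_rank_invariance_on_monotone_nonlinear(self):
        x = np.linspace(1, 5, 20)
        y = np.exp(x)
        assert correlation(x, y, "spearman").statistic == pytest.approx(1.0)
        assert abs(correlation(x, y, "pearson").statistic) < 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_cohort_pooled_correlations_near_targets(self):
        """Pooled Pearson correlations average near the configured targets
        over repeated seeds (Monte-Carlo check of the copula calibration)."""
        from methylmark import synthetic as syn

        r_am, r_ah = [], []
        for seed in range(30):
            subj = syn.generate_cohort(syn.study_cohort_config(seed=seed))
            r_am.append(correlation(subj["age"], subj["mmse"]).statistic)
            r_ah.append(correlation(subj["age"], subj["methylation_pct"]).statistic)
        assert np.mean(r_am) == pytest.approx(-0.589, abs=0.1)
        assert np.mean(r_ah) == pytest.approx(-0.465, abs=0.1)


class TestPartialCorrelation:
    def test_uncorrelated_confound_reduces_to_raw(self, rng):
        assert partial_correlation_from_r(0.5, 0.0, 0.0) == 0.5

    def test_fully_explained_by_confound_gives_zero(self):
        assert partial_correlation_from_r(0.3 * 0.4, 0.3, 0.4) == pytest.approx(0.0)

    def test_printed_study_values_forward_check(self):
        """Raw r inverted from the published age-adjusted value reproduces it."""
        assert partial_correlation_from_r(0.419, -0.465, -0.589) == pytest.approx(
            0.203, abs=5e-4
        )

    def test_symmetric_in_first_two_arguments(self, rng):
        x, y, z = rng.normal(size=(3, 40))
        a = partial_correlation(x, y, z)
        b = partial_correlation(y, x, z)
        assert a.statistic == pytest.approx(b.statistic)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x, y, z = rng.normal(size=(3, 50))
        y = y + 0.5 * z + 0.3 * x
        res = partial_correlation(x, y, z)
        ref = pingouin.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.statistic == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_value == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-8)

    def test_degenerate_conditioning_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            partial_correlation_from_r(0.5, 1.0, 0.3)


# ---------------------------------------------------------------------------
# ROC


class TestRoc:
    def test_perfect_separation(self):
        res = roc([1, 2, 3, 10, 11], ["AD"] * 3 + ["ctl"] * 2, "lower_is_positive")
        assert res.auc == 1.0
        assert res.sens_at_cutoff == 1.0 and res.spec_at_cutoff == 1.0

    def test_null_scores_auc_half(self, rng):
        scores = rng.normal(size=2000)
        labels = np.where(rng.random(2000) < 0.5, "AD", "ctl")
        res = roc(scores, labels, "lower_is_positive")
        assert res.auc == pytest.approx(0.5, abs=0.05)

    def test_trapezoid_equals_concordance_including_ties(self, rng):
        """The two AUC definitions coincide exactly on random tied data."""
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            res = roc(scores, labels, "lower_is_positive", positive_label=True)
            assert res.auc == pytest.approx(auc_trapezoid(res.points), abs=1e-12)

    def test_direction_flip_complements_auc(self, rng):
        scores = rng.normal(size=100)
        labels = rng.random(100) < 0.4
        lo = roc(scores, labels, "lower_is_positive", positive_label=True)
        hi = roc(scores, labels, "higher_is_positive", positive_label=True)
        assert lo.auc == pytest.approx(1.0 - hi.auc)

    def test_agrees_with_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        scores = np.round(rng.normal(size=200), 1)
        labels = rng.random(200) < 0.3
        res = roc(scores, labels, "lower_is_positive", positive_label=True)
        ref = sklearn_metrics.roc_auc_score(labels, -scores)
        assert res.auc == pytest.approx(ref, abs=1e-12)

    def test_published_confusion_counts_reproduce_printed_rates(self):
        """71/105 positives detected and 20/23 negatives rejected give the
        published sensitivity 67.62% and specificity 86.96%."""
        sens, spec = 71 / 105, 20 / 23
        assert round(100 * sens, 2) == 67.62
        assert round(100 * spec, 2) == 86.96
        # construct scores realizing exactly that confusion at a cutoff
        pos = np.concatenate([np.full(71, 70.0), np.full(34, 90.0)])
        neg = np.concatenate([np.full(3, 70.0), np.full(20, 90.0)])
        scores = np.concatenate([pos, neg])
        labels = np.array(["AD"] * 105 + ["other"] * 23)
        res = roc(scores, labels, "lower_is_positive")
        pts = res.points.set_index("threshold")
        assert pts.loc[70.0, "sensitivity"] == pytest.approx(sens)
        assert pts.loc[70.0, "specificity"] == pytest.approx(spec)

    def test_youden_tie_broken_toward_specificity(self):
        # thresholds 1.0 and 3.0 share J = 0.5; the more specific (1.0) wins
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([True, False, True, False])
        res = roc(scores, labels, "lower_is_positive", positive_label=True)
        assert res.youden_cutoff == 1.0 and res.spec_at_cutoff == 1.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc([1.0, 2.0], ["AD", "AD"], "lower_is_positive")


# ---------------------------------------------------------------------------
# severity & power


class TestSeverity:
    @pytest.mark.parametrize(
        "mmse, expected",
        [(25, "mild"), (21, "mild"), (26, "mild"), (12, "moderately_severe"),
         (10, "moderately_severe"), (14, "moderately_severe"), (15, "moderate"),
         (20, "moderate"), (9, "severe"), (0, "severe"), (27, "mild_or_above"),
         (30, "mild_or_above")],
    )
    def test_bins(self, mmse, expected):
        assert classify_severity(mmse) == expected

    def test_out_of_range_rejected(self):
        for bad in (-1, 31):
            with pytest.raises(ValueError):
                classify_severity(bad)


class TestPower:
    def test_null_power_equals_alpha(self):
        res = ttest_power(5.0, 1.0, 10, 5.0, 1.0, 10, alpha=0.05)
        assert res.statistic == pytest.approx(0.05, abs=1e-9)

    def test_huge_effect_power_approaches_one(self):
        res = ttest_power(0.0, 1.0, 20, 10.0, 1.0, 20)
        assert res.statistic > 0.9999

    def test_monotone_in_effect_and_n(self):
        p1 = ttest_power(0.0, 1.0, 10, 0.5, 1.0, 10).statistic
        p2 = ttest_power(0.0, 1.0, 10, 1.0, 1.0, 10).statistic
        p3 = ttest_power(0.0, 1.0, 30, 1.0, 1.0, 30).statistic
        assert p1 < p2 < p3

    def test_agrees_with_statsmodels_equal_variance(self):
        smp = pytest.importorskip("statsmodels.stats.power")
        d = (78.0 - 87.0) / 10.0
        res = ttest_power(78.0, 10.0, 40, 87.0, 10.0, 25)
        ref = smp.TTestIndPower().power(
            effect_size=abs(d), nobs1=40, ratio=25 / 40, alpha=0.05, alternative="two-sided"
        )
        assert res.statistic == pytest.approx(float(ref), abs=1e-6)

    def test_matches_simulation_oracle(self, rng):
        """Analytic power within 2 SE of a 10,000-rep t-test rejection rate."""
        m1, s1, n1, m2, s2, n2 = 77.94, 12.97, 30, 87.20, 12.97, 20
        res = ttest_power(m1, s1, n1, m2, s2, n2, alpha=0.05, method="pooled")
        reps = 10_000
        a = rng.normal(m1, s1, size=(reps, n1))
        b = rng.normal(m2, s2, size=(reps, n2))
        _, p = sps.ttest_ind(a, b, axis=1, equal_var=True)
        rate = float(np.mean(p < 0.05))
        se = math.sqrt(rate * (1 - rate) / reps)
        assert abs(res.statistic - rate) <= 2 * se + 1e-9

    def test_welch_matches_welch_simulation(self, rng):
        m1, s1, n1, m2, s2, n2 = 0.0, 1.0, 15, 0.8, 2.5, 40
        res = ttest_power(m1, s1, n1, m2, s2, n2, alpha=0.05, method="welch")
        reps = 10_000
        a = rng.normal(m1, s1, size=(reps, n1))
        b = rng.normal(m2, s2, size=(reps, n2))
        _, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
        rate = float(np.mean(p < 0.05))
        se = math.sqrt(rate * (1 - rate) / reps)
        assert abs(res.statistic - rate) <= 2 * se + 1e-9
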