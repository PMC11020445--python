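"""The inference chain: CIs, group tests, correlation, ROC, logistic fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ebqspine import (CohortConfig, compare_groups, logistic_fit, or_from_coef,
                      pearson, per_level_summary, roc, simulate_cohort, t_ci_mean)
from ebqspine.stats import RankDeficiencyError, SeparationError, analyze_cohort
from oracles import auc_pair_count


class TestTCI:
    @pytest.mark.parametrize("mean,sd,n,expected", [
        (-1.62, 1.34, 23, (-2.20, -1.04)),   # subsidence-group T-score
        (-0.95, 1.40, 158, (-1.17, -0.73)),  # whole-cohort T-score
        (4.81, 0.91, 17, (4.34, 5.28)),      # C6/7 EBQ
        (3.88, 1.04, 12, (3.22, 4.54)),      # C3/4 EBQ
    ])
    def test_reproduces_reference_bounds_at_2dp(self, mean, sd, n, expected):
        lo, hi = t_ci_mean(mean, sd, n)
        assert (round(lo, 2), round(hi, 2)) == expected

    def test_zero_sd_collapses_to_point(self):
        assert t_ci_mean(4.0, 0.0, 9) == (4.0, 4.0)

    def test_needs_two_observations(self):
        with pytest.raises(ValueError, match="n >= 2"):
            t_ci_mean(1.0, 1.0, 1)

    def test_coverage_of_t_interval(self):
        """Over 2000 simulated normal samples the 95% t interval covers the
        true mean 95% +/- 1.5%."""
        rng = np.random.default_rng(0)
        samples = rng.normal(3.0, 2.0, size=(2000, 20))
        means = samples.mean(axis=1)
        sds = samples.std(axis=1, ddof=1)
        half = sps.t.ppf(0.975, 19) * sds / np.sqrt(20)
        covered = (means - half <= 3.0) & (3.0 <= means + half)
        assert abs(covered.mean() - 0.95) <= 0.015


class TestCompareGroups:
    def _frame(self, x, y, **extra):
        df = pd.DataFrame({"v": np.concatenate([x, y]),
                           "subsided": [0] * len(x) + [1] * len(y)})
        for k, v in extra.items():
            df[k] = v
        return df

    def test_identical_groups_give_p_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        res = compare_groups(self._frame(x, x), "v")
        assert res.test_used == "student_t"
        assert res.p_value == pytest.approx(1.0)

    def test_identical_skewed_groups_fall_back_to_mann_whitney(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(size=60) ** 3
        res = compare_groups(self._frame(x, x), "v")
        assert res.test_used == "mann_whitney"
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_are_significant(self):
        rng = np.random.default_rng(3)
        res = compare_groups(self._frame(rng.normal(0, 1, 50), rng.normal(5, 1, 50)), "v")
        assert res.p_value < 1e-10

    def test_group_summaries_carry_t_cis(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(2, 1, 30), rng.normal(2.5, 1, 20)
        res = compare_groups(self._frame(x, y), "v")
        s = res.groups[0]
        lo, hi = t_ci_mean(s["mean"], s["sd"], s["n"])
        assert s["ci95"] == pytest.approx((lo, hi))
        assert lo < s["mean"] < hi

    def test_categorical_uses_uncorrected_chi_square(self):
        df = pd.DataFrame({
            "sex": ["M"] * 30 + ["F"] * 20 + ["M"] * 10 + ["F"] * 15,
            "subsided": [0] * 50 + [1] * 25,
        })
        res = compare_groups(df, "sex")
        table = pd.crosstab(df["sex"], df["subsided"]).values
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        assert res.test_used == "chi_square"
        assert res.p_value == pytest.approx(p)

    def test_degenerate_categorical_margin_rejected(self):
        df = pd.DataFrame({"smoker": [0] * 20, "subsided": [0] * 10 + [1] * 10})
        with pytest.raises(ValueError, match="degenerate"):
            compare_groups(df, "smoker")


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_null_scatter_is_near_zero(self):
        rng = np.random.default_rng(5)
        assert abs(pearson(rng.normal(size=10000), rng.normal(size=10000)).r) < 0.03

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r0 = pearson(x, y).r
        assert pearson(3.2 * x - 7, 0.5 * y + 11).r == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [1, 2, 3])


class TestRoc:
    def test_perfect_separation(self):
        res = roc([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert 2 < res.cutoff < 3
        assert res.cutoff_sensitivity == 1.0 and res.cutoff_specificity == 1.0
        assert res.youden_j == 1.0

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        n1, n0 = labels.sum(), (1 - labels).sum()
        tol = 3 * np.sqrt((1 / n0 + 1 / n1) / 12)
        assert abs(roc(scores, labels).auc - 0.5) < tol

    def test_auc_equals_pair_count_on_random_fixtures(self):
        """Rank-based AUC equals the O(n^2) concordant-pair oracle exactly,
        including ties, on 50 random fixtures."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            scores = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc(scores, labels).auc == pytest.approx(
                auc_pair_count(scores, labels), abs=1e-12)

    def test_auc_equals_mann_whitney_u(self):
        rng = np.random.default_rng(9)
        scores = np.round(rng.normal(size=300), 1)
        labels = rng.integers(0, 2, size=300)
        n1, n0 = labels.sum(), 300 - labels.sum()
        u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                             alternative="two-sided").statistic
        assert roc(scores, labels).auc == pytest.approx(u / (n0 * n1), abs=1e-12)

    def test_youden_cutoff_beats_every_threshold(self):
        rng = np.random.default_rng(10)
        scores = np.round(rng.normal(size=200) + rng.integers(0, 2, 200), 1)
        labels = rng.integers(0, 2, size=200)
        res = roc(scores, labels)
        j = res.sensitivity + res.specificity - 1
        assert res.youden_j == pytest.approx(j.max(), abs=1e-12)
        assert res.youden_j >= j.max() - 1e-12

    def test_j_ties_break_toward_specificity(self):
        res = roc([1, 2, 3, 4], [0, 1, 0, 1])
        assert res.cutoff == pytest.approx(3.5)
        assert res.cutoff_specificity == 1.0 and res.cutoff_sensitivity == 0.5

    def test_monotone_transform_leaves_auc_and_partition(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=120)
        labels = (scores + rng.normal(size=120) > 0).astype(int)
        a = roc(scores, labels)
        b = roc(np.exp(scores), labels)
        assert b.auc == pytest.approx(a.auc, abs=1e-12)
        assert np.array_equal(scores >= a.cutoff, np.exp(scores) >= b.cutoff)

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=150)
        labels = rng.integers(0, 2, size=150)
        res = roc(scores, labels)
        assert np.all(np.diff(res.sensitivity) <= 1e-12)
        assert np.all(np.diff(res.specificity) >= -1e-12)
        lo, hi = res.auc_ci95
        assert 0 <= lo <= res.auc <= hi <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc([1, 2, 3], [1, 1, 1])


class TestLogisticFit:
    def _sim(self, n, seed, beta0=-1.0, beta1=1.2, beta2=0.0):
        rng = np.random.default_rng(seed)
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        from scipy.special import expit
        p = expit(beta0 + beta1 * x1 + beta2 * x2)
        return pd.DataFrame({"x1": x1, "x2": x2,
                             "subsided": (rng.random(n) < p).astype(int)})

    def test_null_covariate_within_three_se(self):
        df = self._sim(5000, seed=13, beta2=0.0)
        est = logistic_fit(df, ["x1", "x2"]).params["x2"]
        assert abs(est.B) < 3 * est.se

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        df = self._sim(800, seed=14, beta2=-0.7)
        ours = logistic_fit(df, ["x1", "x2"])
        ref = sm.Logit(df["subsided"], sm.add_constant(df[["x1", "x2"]])).fit(disp=0)
        assert ours.params["x1"].B == pytest.approx(ref.params["x1"], abs=1e-8)
        assert ours.params["x1"].se == pytest.approx(ref.bse["x1"], rel=1e-6)
        assert ours.params["x1"].p == pytest.approx(ref.pvalues["x1"], rel=1e-6)

    def test_score_equations_hold_at_convergence(self):
        from scipy.special import expit
        df = self._sim(600, seed=15)
        fit = logistic_fit(df, ["x1", "x2"])
        assert fit.converged
        beta = np.array([fit.params[k].B for k in ("intercept", "x1", "x2")])
        X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
        resid = df["subsided"].to_numpy() - expit(X @ beta)
        assert np.abs(X.T @ resid).max() < 1e-6
        for est in fit.params.values():
            assert est.or_ == pytest.approx(np.exp(est.B), rel=1e-15)
            assert est.or_ci95[0] < est.or_ < est.or_ci95[1]

    def test_separation_detected(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=150)
        df = pd.DataFrame({"x": x, "subsided": (x > 0).astype(int)})
        with pytest.raises(SeparationError):
            logistic_fit(df, ["x"])

    def test_rank_deficiency_names_column(self):
        df = self._sim(200, seed=17)
        df["x1_copy"] = df["x1"]
        with pytest.raises(RankDeficiencyError, match="x1_copy"):
            logistic_fit(df, ["x1", "x1_copy"])

    def test_binary_category_auto_encoded(self):
        df = self._sim(400, seed=18)
        df["sex"] = np.where(df["x2"] > 0, "M", "F")
        fit = logistic_fit(df, ["x1", "sex"])
        assert "sex[M]" in fit.params


class TestOrFromCoef:
    @pytest.mark.parametrize("b,expected", [(0.405, 1.499), (-2.126, 0.119), (0.0, 1.0)])
    def test_reference_odds_ratios(self, b, expected):
        assert round(or_from_coef(b), 3) == expected


class TestPerLevelSummary:
    def test_constant_single_level(self):
        df = pd.DataFrame({"level": ["C5/6"] * 5, "ebq": [4.0] * 5,
                           "subsided": [0] * 5})
        (s,) = per_level_summary(df)
        assert s.mean == 4.0 and s.ci95 == (4.0, 4.0)

    def test_small_levels_omitted_with_warning(self):
        df = pd.DataFrame({"level": ["C5/6"] * 5 + ["C3/4"],
                           "ebq": [4.0, 4.1, 4.2, 4.3, 4.4, 9.9],
                           "subsided": [0] * 6})
        with pytest.warns(UserWarning, match="C3/4"):
            out = per_level_summary(df)
        assert [s.level for s in out] == ["C5/6"]

    def test_configured_gradient_recovered_in_order(self):
        """A configured craniocaudal EBQ gradient shows up monotone in the
        per-level means of the non-subsided patients."""
        cfg = CohortConfig(n_patients=4000,
                           ebq_level_offsets={"C3/4": -0.6, "C4/5": -0.2,
                                              "C5/6": 0.2, "C6/7": 0.6})
        df, _ = simulate_cohort(cfg, seed=19)
        means = [s.mean for s in per_level_summary(df)]
        assert len(means) == 4
        assert all(b > a for a, b in zip(means, means[1:]))


def test_analyze_cohort_bundle(default_cohort_cfg):
    df, _ = simulate_cohort(default_cohort_cfg, seed=20)
    res = analyze_cohort(df)
    assert res["n"] == default_cohort_cfg.n_patients
    variables = {gs.variable for gs in res["table1"]}
    assert {"age", "sex", "ebq", "tscore"} <= variables
    assert "ebq" in res["table2"].params
    assert 0 <= res["roc"].auc <= 1
    assert -1 <= res["correlation"].r <= 1
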