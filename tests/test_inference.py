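"""Composites, robust regression, White's test and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest

from navskill import inference as inf
from navskill.inference import (
    CATEGORY_TREE,
    build_category_composites,
    critical_correlation,
    one_sample_t,
    paired_contrast,
    pearson_with_critical,
    rm_anova_gg,
    robust_regression,
    sidak_threshold,
    white_test,
)

TASK_COLS = ["ROT", "MOV", "RWM", "MWM", "RFM", "MFM", "CHA", "CWM"]


class TestComposites:
    def test_membership_follows_classification_tree(self):
        assert CATEGORY_TREE["dynamic"] == ("CHA", "CWM")
        assert set(CATEGORY_TREE["remembered"]) == {"RFM", "MFM"}
        # each static task sits on exactly one side of every dimension
        for t in TASK_COLS:
            assert (t in CATEGORY_TREE["static"]) != (t in CATEGORY_TREE["dynamic"])
            assert (t in CATEGORY_TREE["egocentric"]) != (t in CATEGORY_TREE["allocentric"])
            assert (t in CATEGORY_TREE["perceived"]) != (t in CATEGORY_TREE["remembered"])

    def test_dynamic_composite_is_mean_of_chase_tasks(self, rng):
        z = pd.DataFrame(rng.normal(size=(10, 8)), columns=TASK_COLS)
        comps = build_category_composites(z)
        np.testing.assert_allclose(comps["dynamic"], z[["CHA", "CWM"]].mean(axis=1))

    def test_all_zero_matrix_gives_zero_composites(self):
        z = pd.DataFrame(np.zeros((5, 8)), columns=TASK_COLS)
        assert (build_category_composites(z) == 0).all().all()

    def test_singleton_category_passthrough(self, rng):
        z = pd.DataFrame(rng.normal(size=(6, 8)), columns=TASK_COLS)
        comps = build_category_composites(z, {"only_chase": ("CHA",)})
        np.testing.assert_allclose(comps["only_chase"], z["CHA"])

    def test_unknown_task_code_rejected(self, rng):
        z = pd.DataFrame(rng.normal(size=(6, 8)), columns=TASK_COLS)
        with pytest.raises(ValueError, match="XXX"):
            build_category_composites(z, {"bad": ("XXX",)})


class TestRobustRegression:
    def test_exact_line_recovers_slope(self):
        x = np.array([0.0, 1.0, 2.0, 5.0, 9.0, 10.0])
        res = robust_regression(x, 2 * x + 1, run_white=False)
        assert res.beta == pytest.approx(2.0)

    def test_matches_sandwich_matrix_oracle(self, rng):
        """HC3 covariance rebuilt from the raw matrix formula."""
        for _ in range(10):
            n = int(rng.integers(10, 60))
            x = rng.normal(size=n)
            y = 0.3 * x + rng.normal(size=n)
            X = np.column_stack([np.ones(n), x])
            XtXi = np.linalg.inv(X.T @ X)
            beta = XtXi @ X.T @ y
            r = y - X @ beta
            h = np.einsum("ij,jk,ik->i", X, XtXi, X)
            u = r / (1 - h)
            V = XtXi @ (X.T * u**2) @ X @ XtXi
            res = robust_regression(x, y)
            assert abs(res.beta - beta[1]) < 1e-8
            assert abs(res.se - np.sqrt(V[1, 1])) < 1e-8
            assert res.wald_chi2 == pytest.approx((res.beta / res.se) ** 2)

    def test_null_rejection_rate_calibrated(self):
        """Monte-Carlo calibration under the null (no association).

        The Wald chi-square reference is asymptotic: at n = 100 the
        rejection rate sits within 1.5 pp of the nominal 5%; at n = 20 the
        HC3 chi-square test shows the known mild small-sample inflation
        (documented, bounded below 9%).
        """
        rng = np.random.default_rng(2024)
        rej100 = sum(
            robust_regression(rng.normal(size=100), rng.normal(size=100), run_white=False).p_value
            < 0.05
            for _ in range(5000)
        )
        assert rej100 / 5000 == pytest.approx(0.05, abs=0.015)
        rej20 = sum(
            robust_regression(rng.normal(size=20), rng.normal(size=20), run_white=False).p_value
            < 0.05
            for _ in range(5000)
        )
        assert 0.04 < rej20 / 5000 < 0.09

    def test_huber_variant_available(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = robust_regression(x, y, method="huber", run_white=False)
        assert res.method == "huber" and 0.5 < res.beta < 1.5

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            robust_regression(np.ones(10), np.arange(10.0))


class TestWhiteTest:
    def test_homoscedastic_rejection_near_alpha(self):
        rng = np.random.default_rng(7)
        rej = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=30)
            y = 0.5 * x + rng.normal(size=30)
            rej += white_test(x, y).p_value < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.02)

    def test_statistic_is_n_times_r2(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(size=20) * (1 + np.abs(x))
        w = white_test(x, y)
        assert w.statistic == pytest.approx(20 * w.aux_r2)
        # n = 20 with aux r2 = 0.37 would give 7.4
        assert 20 * 0.37 == pytest.approx(7.4)

    def test_matches_statsmodels_het_white(self, rng):
        import statsmodels.api as sm
        from statsmodels.stats.diagnostic import het_white

        x = rng.normal(size=40)
        y = x + rng.normal(size=40) * (1 + x**2)
        mine = white_test(x, y)
        lm, lm_p, _, _ = het_white(
            sm.OLS(y, sm.add_constant(x)).fit().resid, sm.add_constant(x)
        )
        assert mine.statistic == pytest.approx(lm, abs=1e-10)
        assert mine.p_value == pytest.approx(lm_p, abs=1e-10)

    def test_perfect_fit_is_degenerate(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="degenerate"):
            white_test(x, 3 * x)


class TestSidak:
    @pytest.mark.parametrize(
        "alpha,k,expected",
        [(0.05, 1, 0.05), (0.05, 8, 0.0064), (0.05, 3, 0.0170)],
    )
    def test_examples(self, alpha, k, expected):
        assert sidak_threshold(alpha, k) == pytest.approx(expected, abs=5e-5)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            sidak_threshold(0.0, 3)
        with pytest.raises(ValueError):
            sidak_threshold(0.05, 0)


class TestOneSampleT:
    def test_symmetric_values_give_zero(self):
        res = one_sample_t(np.array([0.8, 1.2, 0.9, 1.1]), 1.0)
        assert res.t == pytest.approx(0.0)
        assert res.cohen_d == pytest.approx(0.0)

    def test_effect_size_identity(self, rng):
        # d * sqrt(n) reproduces t on random data
        for _ in range(20):
            v = rng.normal(loc=1.1, scale=0.1, size=int(rng.integers(5, 40)))
            res = one_sample_t(v, 1.0)
            assert res.cohen_d * np.sqrt(len(v)) == pytest.approx(res.t)

    def test_reported_effect_size_convention(self):
        # t = 6.86 with n = 20 implies d = 1.534
        assert 6.86 / np.sqrt(20) == pytest.approx(1.534, abs=5e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t(np.ones(5), 1.0)


class TestPearson:
    def test_critical_r_examples(self):
        assert critical_correlation(0.05, 20) == pytest.approx(0.4227, abs=1e-4)
        assert critical_correlation(0.05, 100000) < 0.01  # vanishes asymptotically

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p, crit = pearson_with_critical(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert crit == pytest.approx(critical_correlation(0.05, 10))


class TestRepeatedMeasures:
    def test_identical_columns_give_zero_F(self):
        M = np.tile(np.arange(6.0)[:, None], (1, 4))
        assert rm_anova_gg(M)["F"] == 0.0

    def test_two_level_F_equals_squared_paired_t(self, rng):
        a = rng.normal(size=15)
        b = a + 0.4 + rng.normal(size=15) * 0.5
        from scipy import stats

        t, _ = stats.ttest_rel(a, b)
        out = rm_anova_gg(np.column_stack([a, b]))
        assert out["F"] == pytest.approx(t**2)
        con = paired_contrast(a, b)
        assert con["F"] == pytest.approx(t**2)
        assert con["cohen_d"] == pytest.approx((a - b).mean() / (a - b).std(ddof=1))

    def test_compound_symmetry_gives_epsilon_one(self, rng):
        # whiten the sample so its covariance is exactly the identity
        # (a compound-symmetric matrix): sphericity holds, GG epsilon = 1
        Z = rng.normal(size=(30, 4))
        Zc = Z - Z.mean(axis=0)
        M = Zc @ np.linalg.inv(np.linalg.cholesky(np.cov(Zc, rowvar=False))).T
        M += np.array([0.0, 0.2, 0.4, 0.1])  # condition effects
        out = rm_anova_gg(M)
        assert out["epsilon"] == pytest.approx(1.0, abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        M = rng.normal(size=(12, 4)) + np.array([0, 0.3, 0.5, 0.2])
        mine = rm_anova_gg(M)
        df = pd.DataFrame(M, columns=list("abcd")).reset_index().melt(id_vars="index")
        aov = pg.rm_anova(
            data=df, dv="value", within="variable", subject="index", correction=True
        )
        assert mine["F"] == pytest.approx(float(aov["F"].iloc[0]))
        assert mine["epsilon"] == pytest.approx(float(aov["eps"].iloc[0]), abs=1e-9)
        assert mine["p_value"] == pytest.approx(float(aov["p_GG_corr"].iloc[0]), abs=1e-9)

    def test_missing_cells_rejected(self):
        M = np.ones((5, 3))
        M[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_gg(M)


class TestStudyAnalyses:
    def test_confirmatory_table_shape_and_flags(self, small_study):
        z, nav = small_study
        tab = inf.confirmatory_analysis(z, nav["mean_ratio"])
        assert list(tab["factor"]) == list(CATEGORY_TREE)
        assert tab.attrs["sidak_level"] == pytest.approx(sidak_threshold(0.05, 8))
        assert set(tab.columns) >= {"chi2", "beta", "p_value", "significant"}

    def test_chase_loaded_factor_predicts_navigation_with_planted_sign(self):
        """In a planted world the factor carrying the chase tasks predicts
        navigation error, and the slope sign agrees with the loading sign."""
        from navskill import pipeline
        from navskill.refa import REFA

        z, nav = pipeline.simulate_and_score(n_agents=200, seed=424)
        res = REFA(z, n_factors=3, n_starts=40).fit(seed=0)
        L = res.loadings_frame(0)
        j = int(L.loc["CHA"].abs().idxmax().lstrip("F")) - 1
        scores = res.factor_scores(0)
        reg = robust_regression(scores[:, j], nav["mean_ratio"].to_numpy())
        assert reg.p_value < sidak_threshold(0.05, 3)
        # worse chase performance (higher error) must mean a higher ratio
        assert np.sign(reg.beta) == np.sign(L.loc["CHA"].iloc[j])

    def test_exploratory_uses_factor_scores(self, small_study):
        from navskill.refa import REFA

        z, nav = small_study
        res = REFA(z, n_factors=3, n_starts=30).fit(seed=0)
        tab = inf.exploratory_analysis(res, nav["mean_ratio"])
        n_sets = len(res.rotation_sets)
        assert len(tab) == 3 * n_sets
        assert tab.attrs["sidak_level"] == pytest.approx(sidak_threshold(0.05, 3))
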