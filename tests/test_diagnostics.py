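import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwgtraj import diagnostics as dg
from gwgtraj import distributions as D
from gwgtraj.engine import FitControl, Linear, ModelSpec, fit_baseline, fit_gamlss


class TestQuantileResiduals:
    def test_no_intercept_closed_form(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"gwg_kg": rng.normal(4.0, 1.5, 400)})
        fit = fit_gamlss(
            df,
            ModelSpec(family="NO",
                      control=FitControl(max_outer=200, deviance_tol=1e-12)),
        )
        r = dg.quantile_residuals(fit)
        y = df.gwg_kg.to_numpy()
        expect = (y - y.mean()) / y.std(ddof=0)
        assert np.max(np.abs(r - expect)) < 1e-6

    def test_observation_at_median_gives_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"gwg_kg": rng.normal(0.0, 1.0, 100)})
        fit = fit_gamlss(df, ModelSpec(family="NO"))
        new = pd.DataFrame({"gwg_kg": [fit.fitted_params["mu"][0]]})
        r = dg.quantile_residuals(fit, new)
        assert abs(r[0]) < 1e-10

    def test_pit_definition_identity(self, clean_fit, clean_sim):
        r = dg.quantile_residuals(fit := clean_fit)
        u = D.family_cdf(fit.family, fit.y_model_scale, fit.param_set())
        expect = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
        assert np.allclose(r, expect)

    def test_correctly_specified_summary(self, clean_fit):
        s = dg.residual_summary(dg.quantile_residuals(clean_fit))
        assert abs(s.mean) < 0.05
        assert abs(s.variance - 1.0) < 0.1
        assert abs(s.skewness) < 0.15
        assert abs(s.kurtosis - 3.0) < 0.4
        assert s.filliben > 0.995

    def test_ks_non_rejection_across_seeds(self):
        # correctly specified fits leave standard-normal residuals
        rejections = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 5000
            x = rng.uniform(0, 10, n)
            df = pd.DataFrame(
                {"x": x, "gwg_kg": 1.0 + 0.5 * x + rng.normal(0, 1.2, n)}
            )
            fit = fit_gamlss(
                df,
                ModelSpec(family="NO", mu=[Linear("x")],
                          control=FitControl(max_outer=100,
                                             deviance_tol=1e-8)),
            )
            r = dg.quantile_residuals(fit)
            if stats.kstest(r, "norm").pvalue < 0.01:
                rejections += 1
        assert rejections == 0

    def test_misspecification_detected(self, clean_sim):
        # a normal fit to skewed heavy-tailed data shows up in the summary
        fit = fit_baseline(clean_sim["obs"], "linear")
        s = dg.residual_summary(dg.quantile_residuals(fit))
        assert abs(s.skewness) > 0.15
        assert s.filliben < 0.999


class TestResidualSummary:
    def test_filliben_one_on_exact_medians(self):
        q = stats.norm.ppf(dg.order_statistic_medians(200))
        s = dg.residual_summary(q)
        assert abs(s.filliben - 1.0) < 1e-12

    def test_kurtosis_monte_carlo_bound(self):
        rng = np.random.default_rng(2)
        s = dg.residual_summary(rng.normal(0, 1, 10_000))
        assert 2.8 < s.kurtosis < 3.2

    def test_ten_value_brute_force_oracle(self):
        r = np.array([-1.3, 0.2, 0.7, -0.5, 1.9, -2.2, 0.1, 0.4, -0.8, 1.1])
        s = dg.residual_summary(r)
        n = r.size
        mean = r.sum() / n
        var = ((r - mean) ** 2).sum() / n
        sk = ((r - mean) ** 3).sum() / n / var ** 1.5
        ku = ((r - mean) ** 4).sum() / n / var ** 2
        m = np.empty(n)
        for i in range(1, n + 1):
            if i == 1:
                m[i - 1] = 1 - 0.5 ** (1 / n)
            elif i == n:
                m[i - 1] = 0.5 ** (1 / n)
            else:
                m[i - 1] = (i - 0.3175) / (n + 0.365)
        fil = np.corrcoef(np.sort(r), stats.norm.ppf(m))[0, 1]
        assert s.mean == pytest.approx(mean)
        assert s.variance == pytest.approx(var)
        assert s.skewness == pytest.approx(sk)
        assert s.kurtosis == pytest.approx(ku)
        assert s.filliben == pytest.approx(fil)

    def test_minimum_size_and_zero_variance(self):
        with pytest.raises(ValueError):
            dg.residual_summary(np.arange(5.0))
        with pytest.raises(ValueError):
            dg.residual_summary(np.full(20, 1.0))


class TestWormPlot:
    def test_zero_deviation_on_exact_medians(self):
        q = stats.norm.ppf(dg.order_statistic_medians(50))
        wp = dg.worm_plot_data(q)
        assert np.max(np.abs(wp.deviation)) < 1e-12

    def test_band_widens_toward_tails(self):
        rng = np.random.default_rng(3)
        wp = dg.worm_plot_data(rng.normal(0, 1, 101))
        half = len(wp) // 2
        left = wp.band.iloc[:half].to_numpy()
        assert np.all(np.diff(left) < 0)  # shrinking toward the centre
        right = wp.band.iloc[half:].to_numpy()
        assert np.all(np.diff(right) > 0)

    def test_25_point_direct_oracle(self):
        rng = np.random.default_rng(4)
        r = rng.normal(0, 1, 25)
        wp = dg.worm_plot_data(r)
        n = 25
        p = dg.order_statistic_medians(n)
        x = stats.norm.ppf(p)
        assert np.allclose(wp.x, x)
        assert np.allclose(wp.deviation, np.sort(r) - x)
        assert np.allclose(
            wp.band, 1.96 * np.sqrt(p * (1 - p) / n) / stats.norm.pdf(x)
        )

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            dg.worm_plot_data(np.arange(10.0))


class TestGeneralizedR2:
    def test_self_comparison_zero(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"gwg_kg": rng.normal(0, 1, 100),
                           "gest_age_weeks": rng.uniform(4, 42, 100)})
        fit = fit_baseline(df, "linear", covariates=False)
        assert dg.generalized_r2(fit, fit) == pytest.approx(0.0)

    def test_formula_arithmetic(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"gwg_kg": rng.normal(0, 1, 100),
                           "gest_age_weeks": rng.uniform(4, 42, 100)})
        fit = fit_baseline(df, "linear", covariates=False)
        fit.deviance = 200.0  # l1 = -100
        fit.n = 100
        fit._null_deviance = 300.0  # l0 = -150
        assert dg.generalized_r2(fit) == pytest.approx(1 - np.exp(-1.0), abs=1e-6)

    def test_brute_force_oracle_on_toy_no_fit(self):
        rng = np.random.default_rng(7)
        n = 200
        t = rng.uniform(4, 42, n)
        df = pd.DataFrame(
            {"gest_age_weeks": t, "gwg_kg": 0.3 * t + rng.normal(0, 2, n)}
        )
        fit = fit_baseline(df, "linear", covariates=False)
        y = df.gwg_kg.to_numpy()
        # brute-force likelihoods of the fitted and intercept-only models
        resid = y - fit.fitted_params["mu"]
        l1 = stats.norm.logpdf(resid, 0, y.std(ddof=0) * 0 + fit.fitted_params["sigma"][0]).sum()
        l0 = stats.norm.logpdf(y - y.mean(), 0, y.std(ddof=0)).sum()
        expect = 1 - np.exp((2 / n) * (l0 - l1))
        assert dg.generalized_r2(fit) == pytest.approx(expect, abs=1e-6)

    def test_mismatched_n_raises(self):
        rng = np.random.default_rng(8)
        d1 = pd.DataFrame({"gwg_kg": rng.normal(0, 1, 100),
                           "gest_age_weeks": rng.uniform(4, 42, 100)})
        f1 = fit_baseline(d1, "linear", covariates=False)
        f2 = fit_baseline(d1.head(60), "linear", covariates=False)
        with pytest.raises(ValueError):
            dg.generalized_r2(f1, f2)


class TestIcc:
    def _toy(self):
        return np.array(
            [
                [9.0, 10.0],
                [8.5, 8.0],
                [7.0, 7.5],
                [10.0, 10.5],
                [6.0, 6.5],
                [8.0, 8.5],
            ]
        )

    def test_identical_columns(self):
        X = self._toy()
        res = dg.icc_two_way(np.column_stack([X[:, 0], X[:, 0]]))
        assert res.icc_absolute == pytest.approx(1.0)
        assert res.icc_consistency == pytest.approx(1.0)

    def test_constant_offset(self):
        X = np.column_stack([self._toy()[:, 0], self._toy()[:, 0] + 2.0])
        res = dg.icc_two_way(X)
        assert res.icc_consistency == pytest.approx(1.0)
        assert res.icc_absolute < 1.0

    def test_brute_force_anova_oracle(self):
        X = self._toy()
        n, k = X.shape
        grand = X.mean()
        msr = k * ((X.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((X.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((X - X.mean(axis=1, keepdims=True)
              - X.mean(axis=0, keepdims=True) + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        icc_c = (msr - mse) / (msr + (k - 1) * mse)
        icc_a = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        res = dg.icc_two_way(X)
        assert res.icc_consistency == pytest.approx(icc_c, abs=1e-10)
        assert res.icc_absolute == pytest.approx(icc_a, abs=1e-10)

    def test_against_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        subj = rng.normal(0, 2, 40)
        X = np.column_stack(
            [subj + rng.normal(0, 0.5, 40), subj + 0.3 + rng.normal(0, 0.5, 40)]
        )
        res = dg.icc_two_way(X)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "rater": np.tile(["a", "b"], 40),
                "score": X.ravel(),
            }
        )
        tbl = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        assert res.icc_absolute == pytest.approx(
            tbl.loc["ICC(A,1)", "ICC"], abs=1e-9
        )
        assert res.icc_consistency == pytest.approx(
            tbl.loc["ICC(C,1)", "ICC"], abs=1e-9
        )
        assert res.ci_consistency == pytest.approx(
            tuple(tbl.loc["ICC(C,1)", "CI95"]), abs=2e-2
        )
        assert res.ci_absolute == pytest.approx(
            tuple(tbl.loc["ICC(A,1)", "CI95"]), abs=2e-2
        )

    def test_invariance_properties(self):
        X = self._toy()
        a = dg.icc_two_way(X)
        b = dg.icc_two_way(X * 3.7)  # common rescaling
        assert b.icc_absolute == pytest.approx(a.icc_absolute)
        assert b.icc_consistency == pytest.approx(a.icc_consistency)
        c = dg.icc_two_way(np.column_stack([X[:, 0], X[:, 1] + 5.0]))
        assert c.icc_consistency == pytest.approx(a.icc_consistency)
        assert c.icc_absolute != pytest.approx(a.icc_absolute)

    def test_consistency_at_least_absolute(self):
        # sample-wise the ordering requires the occasion mean square to be
        # at least the error mean square; a systematic offset ensures that
        rng = np.random.default_rng(10)
        for _ in range(5):
            subj = rng.normal(0, 1, 20)
            X = np.column_stack(
                [subj + rng.normal(0, 0.3, 20),
                 subj + rng.normal(0.8, 0.3, 20)]
            )
            res = dg.icc_two_way(X)
            assert res.icc_consistency >= res.icc_absolute - 1e-12
            assert res.icc_absolute <= 1.0 and res.icc_consistency <= 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            dg.icc_two_way(np.ones((2, 2)))
        with pytest.raises(ValueError):
            dg.icc_two_way(np.ones((10, 2)))
        with pytest.raises(ValueError):
            dg.icc_two_way(np.ones((10, 3)))

    def test_reliability_on_synthetic_first_visits(self, noisy_sim):
        # self-reported baseline vs first measured weight: high ICC by
        # construction (both equal the true weight up to ~0.7 kg errors)
        cohort, visits = noisy_sim["cohort"], noisy_sim["visits"]
        first = (
            visits.sort_values(["woman_id", "gest_age_weeks"])
            .groupby("woman_id")
            .first()
            .reset_index()
        )
        early = first[first.gest_age_weeks <= 10.0]
        pairs = early.merge(
            cohort[["woman_id", "prepreg_weight_kg"]], on="woman_id"
        )[["prepreg_weight_kg", "weight_kg"]]
        res = dg.icc_two_way(pairs.to_numpy())
        assert res.icc_absolute > 0.9
        assert res.icc_consistency > 0.9
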